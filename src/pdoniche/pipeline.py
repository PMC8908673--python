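"""End-to-end study orchestration: simulate -> normalize -> classify ->
niche-score -> dose-response -> correlate -> report.

Stages communicate through files (TSV/CSV/JSON), so each stage is
independently runnable and the whole run is reproducible from its config and
seed. Stages whose inputs are absent are skipped and recorded as such; a
failing stage is marked failed and its downstream dependents are skipped.
The serialized report is deterministic given the seed (timings go to the log,
not the report).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import io as pio
from .doseresponse import (
    DoseResponseDataset,
    compare_subtypes,
    drug_sensitivity,
    normalize_to_reference,
    spearman_niche_vs_auc,
)
from .expression import (
    correlate_with_score,
    extract_top_bottom,
    log2_quantile_normalize,
    moffitt_classify,
)
from .growth import assign_niche_subtype, niche_dependency_score
from .imaging import apply_area_filter, segment_objects, stain_positive_fraction
from .qpcr import delta_delta_ct
from .simulate import ScenarioConfig, default_scenario, write_scenario

logger = logging.getLogger("pdoniche.pipeline")

__all__ = ["RunConfig", "StudyReport", "run_pipeline"]

DEFAULT_PARAMS = {
    "k": 1000,
    "min_area_um2": 2000.0,
    "reference_doses": {"gemcitabine": 0.001, "simvastatin": 0.001},
    "rspo_reference": {"drugs": ["RSPO1", "RSPO3"], "reference_drug": "RSPO1",
                       "reference_dose": 1000.0},
    "niche_threshold": None,
    "include_samples": None,
    "basal_signature": "basal",
    "classical_signature": "classical",
    "qpcr_reference_gene": "GAPDH",
    "qpcr_reference_condition": "2D_SM",
}


@dataclass
class RunConfig:
    """Paths to inputs (or a simulate block), analysis parameters, seed, outdir."""

    outdir: Path
    seed: int = 0
    simulate: ScenarioConfig | None = None
    inputs: dict[str, Path] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        self.inputs = {k: Path(v) for k, v in self.inputs.items()}
        merged = dict(DEFAULT_PARAMS)
        merged.update(self.params or {})
        self.params = merged

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.get("simulate")
        if sim is True:
            sim = default_scenario(seed=int(raw.get("seed", 0)))
        elif isinstance(sim, dict):
            sim = ScenarioConfig.from_dict(sim)
        cfg = cls(
            outdir=raw["outdir"],
            seed=int(raw.get("seed", 0)),
            simulate=sim,
            inputs=raw.get("inputs", {}) or {},
            params=raw.get("params", {}) or {},
        )
        missing = [str(p) for p in cfg.inputs.values() if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input path(s): {missing}")
        return cfg

    def canonical(self) -> dict:
        return {
            "seed": self.seed,
            "params": _jsonable(self.params),
            "inputs": {k: str(v) for k, v in sorted(self.inputs.items())},
            "simulate": self.simulate.to_dict() if self.simulate else None,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


@dataclass
class StudyReport:
    provenance: dict
    stages: dict[str, dict] = field(default_factory=dict)
    results: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(
            {"provenance": self.provenance, "stages": self.stages,
             "results": _jsonable(self.results)},
            indent=2, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path) -> "StudyReport":
        d = json.loads(Path(path).read_text())
        return cls(provenance=d["provenance"], stages=d["stages"],
                   results=d["results"])

    @property
    def failed(self) -> bool:
        return any(s["status"] == "failed" for s in self.stages.values())

    def report_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()


class _StageRunner:
    def __init__(self, report: StudyReport):
        self.report = report

    def run(self, name: str, fn, requires: tuple[str, ...] = ()):
        for dep in requires:
            status = self.report.stages.get(dep, {}).get("status")
            if status != "completed":
                self.report.stages[name] = {
                    "status": "skipped", "reason": f"dependency {dep!r} {status}"}
                logger.info("stage %s skipped (dependency %s %s)", name, dep, status)
                return None
        t0 = time.perf_counter()
        try:
            out = fn()
        except _SkipStage as exc:
            self.report.stages[name] = {"status": "skipped", "reason": str(exc)}
            logger.info("stage %s skipped: %s", name, exc)
            return None
        except Exception as exc:
            self.report.stages[name] = {"status": "failed", "error": str(exc)}
            logger.exception("stage %s failed", name)
            return None
        self.report.stages[name] = {"status": "completed"}
        logger.info("stage %s completed in %.2fs", name, time.perf_counter() - t0)
        return out


class _SkipStage(Exception):
    pass


def run_pipeline(cfg: RunConfig) -> StudyReport:
    """Execute every stage whose inputs are present and write the study report."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = StudyReport(provenance={
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "pdoniche_version": __version__,
    })
    runner = _StageRunner(report)
    p = cfg.params
    inputs = dict(cfg.inputs)

    # -- simulate -----------------------------------------------------------
    def _simulate():
        scenario = cfg.simulate
        paths = write_scenario(scenario, outdir / "inputs")
        for key in ("expression", "signatures", "growth", "dose_response",
                    "qpcr", "images"):
            if key in paths:
                inputs.setdefault(key, paths[key])
        return paths

    if cfg.simulate is not None:
        runner.run("simulate", _simulate)

    # -- expression subtyping ----------------------------------------------
    state: dict = {}

    def _expression():
        if "expression" not in inputs or "signatures" not in inputs:
            raise _SkipStage("no expression/signature inputs")
        expr = pio.read_expression_tsv(inputs["expression"], scale="raw")
        sigs = pio.read_gmt(inputs["signatures"])
        for key in (p["basal_signature"], p["classical_signature"]):
            if key not in sigs:
                raise ValueError(f"signature {key!r} not found in GMT")
        norm = log2_quantile_normalize(expr)
        scores = moffitt_classify(
            norm, sigs[p["basal_signature"]], sigs[p["classical_signature"]])
        state["expression"] = norm
        rows = [{
            "sample_id": s.sample_id, "z_basal_sum": s.z_basal_sum,
            "z_classical_sum": s.z_classical_sum,
            "total_score": s.total_score, "label": s.label,
        } for s in scores]
        report.results["subtype_scores"] = rows
        import pandas as pd
        pio.write_table(pd.DataFrame(rows), outdir / "subtype_scores.tsv")
        return scores

    runner.run("expression_subtyping", _expression)

    # -- growth / niche dependency -------------------------------------------
    def _growth():
        if "growth" not in inputs:
            raise _SkipStage("no growth input")
        records = pio.read_growth_csv(inputs["growth"])
        samples = sorted(records.loc[~records["is_blank"], "sample_id"].unique())
        scores = {sid: niche_dependency_score(records, sid) for sid in samples}
        include = p["include_samples"]
        labels, policy = assign_niche_subtype(
            scores, threshold=p["niche_threshold"], include=include)
        report.results["niche_scores"] = {
            sid: {"fold_niche": s.fold_niche, "fold_serum": s.fold_serum,
                  "score": s.score, "subtype": s.subtype}
            for sid, s in scores.items()}
        report.results["niche_subtype_policy"] = policy
        import pandas as pd
        pio.write_table(pd.DataFrame([
            {"sample_id": sid, **report.results["niche_scores"][sid]}
            for sid in samples]), outdir / "niche_scores.tsv")
        return scores, labels

    growth_out = runner.run("growth_niche", _growth)

    # -- correlation ranking --------------------------------------------------
    def _correlate():
        if growth_out is None or "expression" not in state:
            raise _SkipStage("needs expression and growth stages")
        scores, _labels = growth_out
        norm = state["expression"]
        per_sample = {sid: s.score for sid, s in scores.items()
                      if sid in norm.sample_ids}
        if len(per_sample) < 3:
            raise _SkipStage("fewer than 3 samples with both expression and score")
        ranking = correlate_with_score(norm, per_sample)
        k = int(p["k"])
        top, bottom = extract_top_bottom(ranking, k=k)
        report.results["correlation"] = {
            "score_name": ranking.score_name,
            "n_ranked": len(ranking.entries),
            "n_excluded": ranking.n_excluded,
            "k": k, "top": top, "bottom": bottom,
        }
        ranking.to_frame().to_csv(outdir / "correlation_ranking.tsv",
                                  sep="\t", index=False)
        return ranking

    runner.run("correlation_ranking",
               _correlate, requires=("expression_subtyping", "growth_niche"))

    # -- dose response --------------------------------------------------------
    def _dose():
        if "dose_response" not in inputs:
            raise _SkipStage("no dose-response input")
        df = pio.read_dose_csv(inputs["dose_response"])
        rspo = p["rspo_reference"]
        rspo_drugs = set(rspo["drugs"]) & set(df["drug"])
        sens = []
        fits = {}
        # screen drugs: normalize to the drug's own reference dose per sample
        for drug, ref_dose in p["reference_doses"].items():
            sub = df[df["drug"] == drug]
            if sub.empty:
                continue
            norm = normalize_to_reference(sub, ref_dose)
            for sid, g in norm.groupby("sample_id"):
                ds = DoseResponseDataset(
                    drug=drug, sample_id=str(sid),
                    dose=g["dose"].to_numpy(), response=g["response"].to_numpy(),
                    dose_unit=str(g["dose_unit"].iloc[0]), reference_dose=ref_dose)
                s = drug_sensitivity(ds)
                sens.append(s)
                fits[(drug, str(sid))] = s
        # RSPO potency scenario: both curves normalized to the reference drug's
        # top dose within each sample
        if rspo_drugs:
            sub = df[df["drug"].isin(rspo["drugs"])]
            for sid, g in sub.groupby("sample_id"):
                ref_rows = g[(g["drug"] == rspo["reference_drug"])
                             & np.isclose(g["dose"], rspo["reference_dose"])]
                if ref_rows.empty:
                    raise ValueError(
                        f"RSPO reference dose {rspo['reference_dose']} of "
                        f"{rspo['reference_drug']} absent for sample {sid!r}")
                scale = 100.0 / ref_rows["response"].mean()
                for drug, gg in g.groupby("drug"):
                    ds = DoseResponseDataset(
                        drug=str(drug), sample_id=str(sid),
                        dose=gg["dose"].to_numpy(),
                        response=gg["response"].to_numpy() * scale,
                        dose_unit=str(gg["dose_unit"].iloc[0]),
                        reference_dose=rspo["reference_dose"])
                    sens.append(drug_sensitivity(ds))
        report.results["drug_sensitivity"] = [
            {"drug": s.drug, "sample_id": s.sample_id, "ec50": s.ec50,
             "auc": s.auc, "dose_range": list(s.dose_range)} for s in sens]
        import pandas as pd
        pio.write_table(pd.DataFrame(report.results["drug_sensitivity"]),
                        outdir / "drug_sensitivity.tsv")
        return sens

    sens_out = runner.run("dose_response", _dose)

    # -- subtype comparisons --------------------------------------------------
    def _compare():
        if sens_out is None or growth_out is None:
            raise _SkipStage("needs dose-response and growth stages")
        scores, labels = growth_out
        score_vals = {sid: s.score for sid, s in scores.items()}
        comparisons = {}
        for drug in sorted(p["reference_doses"]):
            group = [s for s in sens_out
                     if s.drug == drug and s.sample_id in labels]
            if len(group) < 4:
                continue
            cmp_res = compare_subtypes(group, labels)
            rho, rho_p = spearman_niche_vs_auc(score_vals, group)
            comparisons[drug] = {
                "group_means": cmp_res.group_means,
                "group_n": cmp_res.group_n,
                "t_statistic": cmp_res.t_statistic,
                "p_value": cmp_res.p_value,
                "members": cmp_res.members,
                "spearman_rho": rho, "spearman_p": rho_p,
            }
        report.results["subtype_comparisons"] = comparisons
        return comparisons

    runner.run("subtype_comparison", _compare,
               requires=("dose_response", "growth_niche"))

    # -- imaging --------------------------------------------------------------
    def _imaging():
        if "images" not in inputs:
            raise _SkipStage("no image input")
        img_dir = Path(inputs["images"])
        tifs = sorted(img_dir.glob("*.tif"))
        if not tifs:
            raise _SkipStage("no TIFF images found")
        rows = []
        for path in tifs:
            img = pio.read_image(path)
            if img.channel == "stain":
                rows.append({"image": path.stem, "kind": "stain",
                             "positive_fraction_pct":
                                 stain_positive_fraction(img)})
            else:
                seg = apply_area_filter(segment_objects(img),
                                        threshold_um2=float(p["min_area_um2"]))
                rows.append({"image": path.stem, "kind": "organoid",
                             "organoid_count": seg.organoid_count,
                             "total_area_um2": seg.total_area_um2})
        report.results["imaging"] = rows
        import pandas as pd
        pio.write_table(pd.DataFrame(rows), outdir / "imaging.tsv")
        return rows

    runner.run("organoid_imaging", _imaging)

    # -- qPCR ----------------------------------------------------------------
    def _qpcr():
        if "qpcr" not in inputs:
            raise _SkipStage("no qPCR input")
        records = pio.read_qpcr_csv(inputs["qpcr"])
        ref_gene = p["qpcr_reference_gene"]
        ref_cond = p["qpcr_reference_condition"]
        targets = sorted(set(records["gene"]) - {ref_gene})
        folds = {}
        for gene in targets:
            rels = delta_delta_ct(records, gene, ref_gene, ref_cond)
            folds[gene] = {r.condition: r.fold for r in rels}
        report.results["qpcr_folds"] = folds
        return folds

    runner.run("qpcr_quant", _qpcr)

    report.to_json(outdir / "report.json")
    return report
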