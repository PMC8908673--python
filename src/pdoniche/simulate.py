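"""Seeded synthetic study generator for the PDO niche-dependency pipeline.

One :class:`ScenarioConfig` describes a full organoid study design — sample
grades and designed niche-dependency scores, expression signature effects,
medium-dependent growth, per-drug 4PL truth curves, calibrated images and a
qPCR panel — and the ``generate_*`` functions emit every input table the
analysis consumes, together with the designed ground truth, so the whole
pipeline runs with no external data.

Default design (8 organoid lines):

* Grade 1 lines (PDO565/571/585) are Classical-signature-high, grow only with
  niche factors, and carry high designed niche-dependency scores.
* Grade 3 lines (PDO497/501) are Basal-signature-high and grow better in
  serum; Grade 2 lines sit in between (PDO573 is Classical-like and plastic).
* Mevalonate-pathway gene expression is linearly coupled to the designed
  niche score on the log2 scale.
* Gemcitabine potency decreases (AUC increases) with the niche score;
  simvastatin potency increases with it; an RSPO1/RSPO3 potency scenario on a
  Grade 1 line uses 4PL truth curves with EC50s of 252.5 and 63.89 ng/ml.

Determinism: the same seed and config produce byte-identical outputs; every
generator draws from its own `numpy` substream so the outputs are independent
of generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skimage import draw as skdraw

from .expression import ExpressionMatrix, GeneSignature
from .growth import NICHE_FACTORS
from .imaging import CalibratedImage
from . import io as pio

__all__ = [
    "SampleDesign", "GrowthDesign", "FourPLTruth", "ImageSpec", "QpcrDesign",
    "ScenarioConfig", "default_scenario",
    "generate_expression", "generate_growth_plates", "generate_dose_response",
    "generate_images", "generate_qpcr", "scenario_truth", "write_scenario",
]

# reported RSPO potencies used as the scenario's generating truth (ng/ml)
RSPO3_EC50 = 63.89
RSPO1_EC50 = 252.5

# substream ids, so each generator is independently deterministic
_STREAMS = {"expression": 1, "growth": 2, "dose": 3, "images": 4, "qpcr": 5}


def _plain(obj):
    """Recursively cast numpy scalars/arrays so YAML/JSON can represent them."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_plain(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), _STREAMS[stream]])


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise with unit mean and the given coefficient of variation."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size=size))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SampleDesign:
    sample_id: str
    grade: int                      # 1 (well) .. 3 (poorly differentiated)
    designed_niche_score: float     # fold(niche)/fold(serum) truth, > 0
    classical_like: bool | None = None  # default: grade 1 -> True, else False

    def __post_init__(self) -> None:
        if self.grade not in (1, 2, 3):
            raise ValueError(f"grade must be 1, 2 or 3 (got {self.grade})")
        if not self.designed_niche_score > 0:
            raise ValueError("designed_niche_score must be > 0")
        if self.classical_like is None:
            self.classical_like = self.grade == 1


@dataclass
class GrowthDesign:
    """Medium-dependent expected day-10 fold changes.

    ``serum_fold_by_grade`` fixes fold(serum) per grade; fold(niche) is the
    sample's designed score times its serum fold, so the designed niche score
    is recoverable by construction. ``dropout_multipliers`` maps each niche
    factor to (classical-like, basal-like) relative-growth multipliers for the
    factor-dropout media.
    """
    serum_fold_by_grade: dict[int, float] = field(
        default_factory=lambda: {1: 1.0, 2: 3.0, 3: 8.0})
    replicate_cv: float = 0.10
    n_replicates: int = 3
    combined_attenuation: float = 0.9   # mild serum inhibition of niche growth
    dropout_multipliers: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "Wnt3a": (1.0, 1.0),      # no line depends on exogenous Wnt
            "RSPO1": (0.35, 0.95),    # Classical-like lines need RSPO
            "Noggin": (0.7, 0.9),
            "EGF": (0.5, 0.75),
            "FGF10": (0.8, 0.9),
            "A83-01": (0.6, 0.85),
        })


@dataclass
class FourPLTruth:
    bottom: float
    top: float
    ec50: float
    hill: float

    def response(self, dose):
        logd = np.log10(np.asarray(dose, dtype=float))
        return self.bottom + (self.top - self.bottom) / (
            1.0 + 10.0 ** ((math.log10(self.ec50) - logd) * self.hill))


@dataclass
class ImageSpec:
    image_id: str
    kind: str                        # "organoid" | "stain"
    grade: int
    um_per_pixel: float = 2.0
    shape: tuple[int, int] = (512, 512)
    object_areas_um2: list[float] = field(default_factory=list)
    positive_fraction: float | None = None  # stain images only


@dataclass
class QpcrDesign:
    true_ct: dict[str, dict[str, float]]   # gene -> condition -> mean Ct
    replicate_sd: float = 0.15
    n_replicates: int = 3
    reference_gene: str = "GAPDH"
    reference_condition: str = "2D_SM"


@dataclass
class ScenarioConfig:
    seed: int = 0
    samples: list[SampleDesign] = field(default_factory=list)
    n_genes: int = 6065                       # total gene universe
    signature_sizes: dict[str, int] = field(
        default_factory=lambda: {"basal": 25, "classical": 25, "mevalonate": 15})
    signature_effect: float = 2.0             # log2 shift of signature genes
    mevalonate_slope: float = 0.8             # log2 units per niche-score unit
    expr_noise_sd: float = 0.5                # log2-additive gaussian SD
    mevalonate_noise_sd: float | None = None  # None -> expr_noise_sd
    growth: GrowthDesign = field(default_factory=GrowthDesign)
    seeding_cells: int = 5000
    blank_lum: float = 200.0
    per_cell_signal: float = 1.5
    drugs: dict[tuple[str, str], FourPLTruth] = field(default_factory=dict)
    dose_grids: dict[str, list[float]] = field(default_factory=dict)
    dose_units: dict[str, str] = field(default_factory=dict)
    dose_noise_cv: float = 0.05
    dose_replicates: int = 3
    images: list[ImageSpec] = field(default_factory=list)
    qpcr: QpcrDesign | None = None
    include_samples: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if not self.samples:
            raise ValueError("scenario has no samples")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids")
        for s in self.samples:
            if not s.designed_niche_score > 0:
                raise ValueError("designed niche scores must be > 0")
        if sum(self.signature_sizes.values()) > self.n_genes:
            raise ValueError("signature sizes exceed the gene universe")
        if any(v < 1 for v in self.signature_sizes.values()):
            raise ValueError("signature sizes must be >= 1")
        for drug, grid in self.dose_grids.items():
            g = np.asarray(grid, dtype=float)
            if (g <= 0).any() or (np.diff(g) <= 0).any():
                raise ValueError(
                    f"dose grid for {drug!r} must be strictly increasing and positive")
        for (drug, sid), truth in self.drugs.items():
            if drug not in self.dose_grids:
                raise ValueError(f"no dose grid for drug {drug!r}")
            if truth.top < truth.bottom:
                raise ValueError(f"4PL truth top < bottom for {(drug, sid)}")
        unknown = set(self.include_samples) - set(ids)
        if unknown:
            raise ValueError(f"include_samples not in design: {sorted(unknown)}")

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["drugs"] = [
            {"drug": drug, "sample_id": sid, **asdict(t)}
            for (drug, sid), t in self.drugs.items()
        ]
        return _plain(d)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        d["samples"] = [SampleDesign(**s) for s in d.get("samples", [])]
        if "growth" in d and isinstance(d["growth"], dict):
            g = dict(d["growth"])
            g["serum_fold_by_grade"] = {
                int(k): float(v) for k, v in g.get("serum_fold_by_grade", {}).items()}
            g["dropout_multipliers"] = {
                k: tuple(v) for k, v in g.get("dropout_multipliers", {}).items()}
            d["growth"] = GrowthDesign(**g)
        d["drugs"] = {
            (e["drug"], e["sample_id"]): FourPLTruth(
                bottom=e["bottom"], top=e["top"], ec50=e["ec50"], hill=e["hill"])
            for e in d.get("drugs", [])
        }
        d["images"] = [
            ImageSpec(**{**im, "shape": tuple(im["shape"])})
            for im in d.get("images", [])
        ]
        if d.get("qpcr"):
            d["qpcr"] = QpcrDesign(**d["qpcr"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_scenario(seed: int = 0) -> ScenarioConfig:
    """The 8-line study design: 3 Grade 1, 3 Grade 2, 2 Grade 3 organoids."""
    samples = [
        SampleDesign("PDO565", 1, 3.5),
        SampleDesign("PDO571", 1, 5.0),
        SampleDesign("PDO585", 1, 4.2),
        SampleDesign("PDO573", 2, 2.2, classical_like=True),
        SampleDesign("PDO578", 2, 0.9),
        SampleDesign("PDO580", 2, 0.8),
        SampleDesign("PDO497", 3, 0.45),
        SampleDesign("PDO501", 3, 0.55),
    ]
    include = ["PDO565", "PDO571", "PDO585", "PDO497", "PDO501", "PDO580"]

    gem = {  # sample -> (bottom %, EC50 nM); resistance rises with niche score
        "PDO497": (2.0, 8.0), "PDO501": (3.0, 10.0), "PDO580": (5.0, 15.0),
        "PDO565": (30.0, 150.0), "PDO585": (35.0, 220.0), "PDO571": (40.0, 300.0),
    }
    simva = {  # reversed: high-niche lines are statin-sensitive (uM)
        "PDO497": (50.0, 50.0), "PDO501": (45.0, 40.0), "PDO580": (38.0, 25.0),
        "PDO565": (10.0, 1.5), "PDO585": (8.0, 1.2), "PDO571": (5.0, 0.8),
    }
    drugs: dict[tuple[str, str], FourPLTruth] = {}
    for sid, (b, e) in gem.items():
        drugs[("gemcitabine", sid)] = FourPLTruth(bottom=b, top=100.0, ec50=e, hill=-1.0)
    for sid, (b, e) in simva.items():
        drugs[("simvastatin", sid)] = FourPLTruth(bottom=b, top=100.0, ec50=e, hill=-1.0)
    # RSPO potency scenario on a Grade 1 line, in raw proliferation-fold units
    drugs[("RSPO1", "PDO585")] = FourPLTruth(bottom=1.0, top=8.0, ec50=RSPO1_EC50, hill=1.0)
    drugs[("RSPO3", "PDO585")] = FourPLTruth(bottom=1.0, top=8.5, ec50=RSPO3_EC50, hill=1.0)

    images = []
    organoid_areas = {
        1: [2500.0, 3200.0, 4100.0, 5000.0, 2000.0, 1500.0, 800.0],
        2: [2600.0, 3000.0, 1900.0, 2200.0],
        3: [5200.0, 2800.0, 1200.0],
    }
    stain_fraction = {1: 0.30, 2: 0.15, 3: 0.05}
    for grade in (1, 2, 3):
        images.append(ImageSpec(
            image_id=f"organoid_g{grade}", kind="organoid", grade=grade,
            um_per_pixel=2.0, shape=(512, 512),
            object_areas_um2=organoid_areas[grade]))
        images.append(ImageSpec(
            image_id=f"stain_g{grade}", kind="stain", grade=grade,
            um_per_pixel=1.0, shape=(200, 200),
            positive_fraction=stain_fraction[grade]))

    qpcr = QpcrDesign(true_ct={
        "GAPDH": {"2D_SM": 18.0, "3D_SM": 18.0, "3D_PDO-CM": 18.0},
        "RSPO1": {"2D_SM": 27.0, "3D_SM": 27.1, "3D_PDO-CM": 26.9},
        "RSPO2": {"2D_SM": 29.0, "3D_SM": 29.0, "3D_PDO-CM": 29.1},
        "RSPO3": {"2D_SM": 28.0, "3D_SM": 27.7, "3D_PDO-CM": 25.0},
        "RSPO4": {"2D_SM": 30.0, "3D_SM": 30.0, "3D_PDO-CM": 30.05},
    })

    cfg = ScenarioConfig(
        seed=seed,
        samples=samples,
        drugs=drugs,
        dose_grids={
            "gemcitabine": list(np.logspace(-3, 4, 8)),
            "simvastatin": list(np.logspace(-3, 2, 6)),
            "RSPO1": list(np.logspace(0, 3, 8)),
            "RSPO3": list(np.logspace(0, 3, 8)),
        },
        dose_units={
            "gemcitabine": "nM", "simvastatin": "uM",
            "RSPO1": "ng/ml", "RSPO3": "ng/ml",
        },
        images=images,
        qpcr=qpcr,
        include_samples=include,
    )
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_expression(
    cfg: ScenarioConfig,
) -> tuple[ExpressionMatrix, dict[str, GeneSignature]]:
    """Raw gene x sample intensities plus the three signature gene sets.

    Log2 means: signature genes sit at a common baseline shifted by
    ``signature_effect`` in the matching samples (classical genes up in
    Classical-like samples, basal genes in the rest); each mevalonate gene's
    log2 mean is baseline + mevalonate_slope x designed niche score; the
    remaining background genes are i.i.d. noise around the baseline.
    """
    cfg.validate()
    rng = _rng(cfg.seed, "expression")
    sizes = cfg.signature_sizes
    n_bg = cfg.n_genes - sum(sizes.values())
    genes = {
        "basal": [f"BASAL{i:03d}" for i in range(sizes["basal"])],
        "classical": [f"CLASS{i:03d}" for i in range(sizes["classical"])],
        "mevalonate": [f"MVA{i:03d}" for i in range(sizes["mevalonate"])],
    }
    bg_genes = [f"BG{i:05d}" for i in range(n_bg)]
    baseline = 7.0
    mva_baseline = 6.0
    n_samples = len(cfg.samples)
    classical_mask = np.array([s.classical_like for s in cfg.samples])
    scores = np.array([s.designed_niche_score for s in cfg.samples])

    rows, index = [], []
    mva_sd = cfg.expr_noise_sd if cfg.mevalonate_noise_sd is None else cfg.mevalonate_noise_sd
    for g in genes["basal"]:
        mean = baseline + cfg.signature_effect * (~classical_mask)
        rows.append(mean + rng.normal(0.0, cfg.expr_noise_sd, n_samples)
                    if cfg.expr_noise_sd else mean.astype(float))
        index.append(g)
    for g in genes["classical"]:
        mean = baseline + cfg.signature_effect * classical_mask
        rows.append(mean + rng.normal(0.0, cfg.expr_noise_sd, n_samples)
                    if cfg.expr_noise_sd else mean.astype(float))
        index.append(g)
    for g in genes["mevalonate"]:
        mean = mva_baseline + cfg.mevalonate_slope * scores
        rows.append(mean + rng.normal(0.0, mva_sd, n_samples) if mva_sd
                    else mean.astype(float))
        index.append(g)
    if n_bg:
        bg = baseline + (rng.normal(0.0, cfg.expr_noise_sd, (n_bg, n_samples))
                         if cfg.expr_noise_sd else np.zeros((n_bg, n_samples)))
        rows.extend(bg)
        index.extend(bg_genes)

    log2 = np.vstack([np.asarray(r, dtype=float) for r in rows])
    data = pd.DataFrame(
        np.power(2.0, log2), index=index,
        columns=[s.sample_id for s in cfg.samples])
    signatures = {name: GeneSignature(name=name, genes=gl)
                  for name, gl in genes.items()}
    return ExpressionMatrix(data=data, scale="raw"), signatures


def designed_fold(cfg: ScenarioConfig, sample: SampleDesign, condition: str) -> float:
    """The designed day-10 fold change for a sample x medium condition."""
    g = cfg.growth
    serum = g.serum_fold_by_grade[sample.grade]
    niche = sample.designed_niche_score * serum
    if condition == "serum":
        return serum
    if condition == "niche":
        return niche
    if condition == "combined":
        return (g.combined_attenuation * niche if sample.classical_like
                else max(niche, serum))
    if condition.startswith("niche-"):
        factor = condition.split("-", 1)[1]
        if factor not in g.dropout_multipliers:
            raise ValueError(f"unknown dropout factor {factor!r}")
        mult = g.dropout_multipliers[factor][0 if sample.classical_like else 1]
        return niche * mult
    raise ValueError(f"unknown condition {condition!r}")


def generate_growth_plates(cfg: ScenarioConfig) -> pd.DataFrame:
    """Well-level luminescence for every sample x medium condition.

    Day-0 control wells read the seeded 5,000 cells; day-10 wells read
    seeded cells x designed fold x lognormal replicate noise. Luminescence is
    blank + cells x per-cell signal; blank wells are emitted per sample batch.
    """
    cfg.validate()
    rng = _rng(cfg.seed, "growth")
    g = cfg.growth
    conditions = ["niche", "serum", "combined"] + [f"niche-{f}" for f in NICHE_FACTORS]
    rows = []
    for s in cfg.samples:
        for rep in range(1, g.n_replicates + 1):
            rows.append((s.sample_id, "blank", 0, rep, cfg.blank_lum, True))
            cells = cfg.seeding_cells * _lognormal_factor(rng, g.replicate_cv)
            rows.append((s.sample_id, "control", 0, rep,
                         cfg.blank_lum + cells * cfg.per_cell_signal, False))
        for cond in conditions:
            fold = designed_fold(cfg, s, cond)
            for rep in range(1, g.n_replicates + 1):
                cells = cfg.seeding_cells * fold * _lognormal_factor(rng, g.replicate_cv)
                rows.append((s.sample_id, cond, 10, rep,
                             cfg.blank_lum + cells * cfg.per_cell_signal, False))
    return pd.DataFrame(rows, columns=pio.GROWTH_COLUMNS)


def generate_dose_response(cfg: ScenarioConfig) -> pd.DataFrame:
    """Replicate responses drawn from each (drug, sample) 4PL truth curve with
    multiplicative lognormal noise at every dose of the drug's grid."""
    cfg.validate()
    rng = _rng(cfg.seed, "dose")
    rows = []
    for (drug, sid), truth in sorted(cfg.drugs.items()):
        grid = np.asarray(cfg.dose_grids[drug], dtype=float)
        unit = cfg.dose_units.get(drug, "")
        clean = truth.response(grid)
        for rep in range(1, cfg.dose_replicates + 1):
            noisy = clean * _lognormal_factor(rng, cfg.dose_noise_cv, size=grid.size)
            for dose, resp in zip(grid, noisy):
                rows.append((drug, sid, dose, unit, rep, resp))
    return pd.DataFrame(rows, columns=pio.DOSE_COLUMNS)


def _place_ellipses(
    spec: ImageSpec, rng: np.random.Generator
) -> tuple[np.ndarray, list[float]]:
    """Draw non-overlapping bright ellipses of the requested um^2 areas.

    Returns the image and the realized per-object areas (drawn pixel count
    x um_per_pixel^2), which differ from the requested areas only by pixel
    discretization.
    """
    h, w = spec.shape
    img = np.full((h, w), 30, dtype=np.uint8)
    realized: list[float] = []
    n = len(spec.object_areas_um2)
    if n == 0:
        return img, realized
    side = math.ceil(math.sqrt(n))
    cell_h, cell_w = h // side, w // side
    for i, area_um2 in enumerate(spec.object_areas_um2):
        area_px = area_um2 / spec.um_per_pixel**2
        ratio = rng.uniform(0.7, 1.0)
        a = math.sqrt(area_px / (math.pi * ratio))   # semi-major (px)
        b = a * ratio
        gy, gx = divmod(i, side)
        cy = gy * cell_h + cell_h // 2
        cx = gx * cell_w + cell_w // 2
        if a >= min(cell_h, cell_w) / 2 - 1:
            raise ValueError(
                f"object of {area_um2} um^2 too large for image {spec.image_id}")
        rr, cc = skdraw.ellipse(cy, cx, b, a, shape=(h, w),
                                rotation=rng.uniform(0.0, math.pi))
        img[rr, cc] = 200
        realized.append(float(rr.size) * spec.um_per_pixel**2)
    return img, realized


def _stain_image(spec: ImageSpec) -> np.ndarray:
    h, w = spec.shape
    img = np.full((h, w), 40, dtype=np.uint8)
    n_pos = round(spec.positive_fraction * h)
    img[:n_pos, :] = 220
    return img


def generate_images(
    cfg: ScenarioConfig,
) -> list[tuple[ImageSpec, CalibratedImage, dict]]:
    """Calibrated images plus per-image ground truth."""
    cfg.validate()
    rng = _rng(cfg.seed, "images")
    out = []
    for spec in cfg.images:
        if spec.kind == "organoid":
            px, realized = _place_ellipses(spec, rng)
            truth = {
                "kind": "organoid",
                "designed_areas_um2": list(spec.object_areas_um2),
                "object_areas_um2": realized,  # as drawn, after discretization
                "n_objects": len(spec.object_areas_um2),
            }
        elif spec.kind == "stain":
            px = _stain_image(spec)
            truth = {"kind": "stain",
                     "positive_fraction": round(spec.positive_fraction * spec.shape[0])
                     / spec.shape[0]}
        else:
            raise ValueError(f"unknown image kind {spec.kind!r}")
        out.append((spec,
                    CalibratedImage(pixels=px, um_per_pixel=spec.um_per_pixel,
                                    channel=spec.kind),
                    truth))
    return out


def generate_qpcr(cfg: ScenarioConfig) -> pd.DataFrame:
    """Replicate Ct values ~ Normal(true mean, replicate SD) per gene x condition."""
    cfg.validate()
    if cfg.qpcr is None:
        raise ValueError("scenario has no qPCR design")
    rng = _rng(cfg.seed, "qpcr")
    q = cfg.qpcr
    rows = []
    for gene, by_cond in sorted(q.true_ct.items()):
        for cond, mean in by_cond.items():
            for rep in range(1, q.n_replicates + 1):
                ct = mean + (rng.normal(0.0, q.replicate_sd) if q.replicate_sd else 0.0)
                rows.append((gene, cond, rep, ct))
    return pd.DataFrame(rows, columns=pio.QPCR_COLUMNS)


# ---------------------------------------------------------------------------
# ground truth and full-scenario output
# ---------------------------------------------------------------------------

def scenario_truth(cfg: ScenarioConfig) -> dict:
    """Designed ground truth emitted next to the data so tests never re-derive it."""
    cfg.validate()
    include = cfg.include_samples or [s.sample_id for s in cfg.samples]
    inc_scores = {s.sample_id: s.designed_niche_score
                  for s in cfg.samples if s.sample_id in include}
    cut = float(np.median(list(inc_scores.values())))
    truth: dict = {
        "samples": {
            s.sample_id: {
                "grade": s.grade,
                "designed_niche_score": s.designed_niche_score,
                "designed_subtype": "Classical" if s.classical_like else "Basal-like",
            }
            for s in cfg.samples
        },
        "include_samples": list(include),
        "niche_subtype": {sid: ("High" if sc > cut else "Low")
                          for sid, sc in inc_scores.items()},
        "drugs": [
            {"drug": drug, "sample_id": sid, **asdict(t)}
            for (drug, sid), t in sorted(cfg.drugs.items())
        ],
    }
    if cfg.qpcr is not None:
        q = cfg.qpcr
        folds = {}
        for gene, by_cond in q.true_ct.items():
            if gene == q.reference_gene:
                continue
            d_ct = {c: by_cond[c] - q.true_ct[q.reference_gene][c] for c in by_cond}
            base = d_ct[q.reference_condition]
            folds[gene] = {c: 2.0 ** -(d_ct[c] - base) for c in d_ct}
        truth["qpcr_fold"] = folds
    truth["images"] = {spec.image_id: t for spec, _, t in generate_images(cfg)}
    return truth


def write_scenario(cfg: ScenarioConfig, outdir) -> dict[str, Path]:
    """Generate and write every pipeline input plus truth.json; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    expr, sigs = generate_expression(cfg)
    paths["expression"] = outdir / "expression.tsv"
    pio.write_expression_tsv(expr, paths["expression"])
    paths["signatures"] = outdir / "signatures.gmt"
    pio.write_gmt(list(sigs.values()), paths["signatures"])

    paths["growth"] = outdir / "growth.csv"
    pio.write_table(generate_growth_plates(cfg), paths["growth"])
    paths["dose_response"] = outdir / "dose_response.csv"
    pio.write_table(generate_dose_response(cfg), paths["dose_response"])
    if cfg.qpcr is not None:
        paths["qpcr"] = outdir / "qpcr.csv"
        pio.write_table(generate_qpcr(cfg), paths["qpcr"])

    img_dir = outdir / "images"
    img_dir.mkdir(exist_ok=True)
    for spec, img, _truth in generate_images(cfg):
        pio.write_image(img, img_dir / f"{spec.image_id}.tif")
    paths["images"] = img_dir

    paths["truth"] = outdir / "truth.json"
    pio.write_json(scenario_truth(cfg), paths["truth"])
    paths["scenario"] = outdir / "scenario.yaml"
    cfg.to_yaml(paths["scenario"])
    return paths
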