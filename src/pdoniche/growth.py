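"""Luminescence-based proliferation analysis and niche-dependency scoring.

Organoid proliferation is read out as CellTiter-Glo-style luminescence: a
blank well defines the medium baseline, each well's signal is the raw reading
minus the blank mean, and growth is the day-10 / day-0 signal ratio. The niche
dependency score of a sample is the ratio of its proliferation fold change in
full niche medium to that in serum medium; samples are split into "High" and
"Low" niche-dependency subtypes.

Records are long-format DataFrames with columns
``sample_id, condition, day, replicate, luminescence, is_blank`` (plus an
optional ``batch`` column for per-plate blanks). Conditions are encoded as
tokens: ``niche``, ``serum``, ``combined``, ``control`` (day-0 reference
wells) and ``niche-<Factor>`` for factor-dropout media.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NICHE_FACTORS",
    "NicheDependencyScore",
    "subtract_blank",
    "fold_change",
    "niche_dependency_score",
    "dropout_relative_proliferation",
    "assign_niche_subtype",
]

#: canonical niche-factor names for dropout conditions
NICHE_FACTORS = ("Wnt3a", "RSPO1", "Noggin", "EGF", "FGF10", "A83-01")

REQUIRED_COLUMNS = ("sample_id", "condition", "day", "replicate",
                    "luminescence", "is_blank")


@dataclass
class NicheDependencyScore:
    sample_id: str
    fold_niche: float
    fold_serum: float
    score: float
    subtype: str | None = None  # "High" | "Low", set by assign_niche_subtype


def _check_records(records: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"growth records missing columns: {missing}")
    if (records["luminescence"] < 0).any():
        raise ValueError("negative raw luminescence")


def subtract_blank(records: pd.DataFrame) -> pd.DataFrame:
    """Blank-subtract raw luminescence.

    The baseline is the mean of blank wells, per ``batch`` if that column is
    present, otherwise global. Returns the non-blank rows with a new
    ``signal`` column; negative differences are clipped to 0 with a warning.
    """
    _check_records(records)
    blanks = records[records["is_blank"].astype(bool)]
    if blanks.empty:
        raise ValueError("no blank well found; cannot establish baseline")
    out = records[~records["is_blank"].astype(bool)].copy()
    if "batch" in records.columns:
        baseline = blanks.groupby("batch")["luminescence"].mean()
        missing = set(out["batch"]) - set(baseline.index)
        if missing:
            raise ValueError(f"no blank well for batch(es): {sorted(missing)}")
        sub = out["luminescence"] - out["batch"].map(baseline)
    else:
        sub = out["luminescence"] - blanks["luminescence"].mean()
    n_neg = int((sub < 0).sum())
    if n_neg:
        warnings.warn(
            f"{n_neg} blank-subtracted signal(s) < 0 clipped to 0", stacklevel=2
        )
    out["signal"] = sub.clip(lower=0.0)
    return out


def _signal(records: pd.DataFrame) -> pd.DataFrame:
    return records if "signal" in records.columns else subtract_blank(records)


def fold_change(
    records: pd.DataFrame,
    sample: str,
    condition: str,
    *,
    day0: int = 0,
    day_final: int = 10,
    control_condition: str = "control",
) -> float:
    """Day-final mean signal under ``condition`` over the day-0 control mean.

    The day-0 control (seeded-cell reading) is shared across the conditions of
    a sample.
    """
    df = _signal(records)
    df = df[df["sample_id"] == sample]
    d0 = df[(df["day"] == day0) & (df["condition"] == control_condition)]
    if d0.empty:
        raise ValueError(f"no day-{day0} control wells for sample {sample!r}")
    d1 = df[(df["day"] == day_final) & (df["condition"] == condition)]
    if d1.empty:
        raise ValueError(
            f"no day-{day_final} wells for sample {sample!r}, "
            f"condition {condition!r}"
        )
    denom = d0["signal"].mean()
    if denom == 0:
        raise ValueError(f"zero day-{day0} control signal for sample {sample!r}")
    return float(d1["signal"].mean() / denom)


def niche_dependency_score(
    records: pd.DataFrame, sample: str, **fold_kwargs
) -> NicheDependencyScore:
    """score = fold change in niche medium / fold change in serum medium."""
    fn = fold_change(records, sample, "niche", **fold_kwargs)
    fs = fold_change(records, sample, "serum", **fold_kwargs)
    if fs == 0:
        raise ValueError(f"zero serum-medium fold change for sample {sample!r}")
    return NicheDependencyScore(
        sample_id=sample, fold_niche=fn, fold_serum=fs, score=fn / fs
    )


def dropout_relative_proliferation(
    records: pd.DataFrame, sample: str, omitted_factor: str, **fold_kwargs
) -> float:
    """Fold change in niche medium lacking one factor, relative to full niche."""
    if omitted_factor not in NICHE_FACTORS:
        raise ValueError(
            f"unknown niche factor {omitted_factor!r}; expected one of {NICHE_FACTORS}"
        )
    f_drop = fold_change(records, sample, f"niche-{omitted_factor}", **fold_kwargs)
    f_full = fold_change(records, sample, "niche", **fold_kwargs)
    if f_full == 0:
        raise ValueError(f"zero full-niche fold change for sample {sample!r}")
    return float(f_drop / f_full)


def assign_niche_subtype(
    scores: dict[str, NicheDependencyScore] | dict[str, float],
    threshold: float | None = None,
    include: list[str] | None = None,
) -> tuple[dict[str, str], dict]:
    """Split samples into High/Low niche-dependency subtypes.

    Policy: a fixed ``threshold`` if given, otherwise a median split over the
    analyzed samples. A sample is "High" iff its score is strictly above the
    cut. ``include`` restricts the analysis to an explicit sample list (the
    grouping used for drug comparisons). Returns (labels, policy_record).
    """
    vals = {
        sid: (s.score if isinstance(s, NicheDependencyScore) else float(s))
        for sid, s in scores.items()
    }
    if include is not None:
        missing = sorted(set(include) - set(vals))
        if missing:
            raise ValueError(f"include-list samples without scores: {missing}")
        vals = {sid: vals[sid] for sid in include}
    if not vals:
        raise ValueError("no samples to assign")
    if threshold is None:
        arr = np.array(list(vals.values()))
        if np.all(arr == arr[0]):
            raise ValueError("all scores equal; median split undefined")
        cut = float(np.median(arr))
        policy = {"policy": "median_split", "cut": cut}
    else:
        cut = float(threshold)
        policy = {"policy": "fixed_threshold", "cut": cut}
    labels = {sid: ("High" if v > cut else "Low") for sid, v in vals.items()}
    policy["samples"] = sorted(vals)
    for sid, s in scores.items():
        if isinstance(s, NicheDependencyScore) and sid in labels:
            s.subtype = labels[sid]
    return labels, policy
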