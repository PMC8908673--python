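"""Relative qPCR quantification by the ddCt method.

Replicate Ct values are averaged on the Ct scale; per condition,
dCt = mean Ct(target) - mean Ct(reference gene); ddCt subtracts the
baseline condition's dCt, and fold = 2**(-ddCt). Amplification efficiency is
fixed at 2 (no efficiency correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["CtRecord", "RelativeExpression", "delta_delta_ct"]

CT_RANGE = (0.0, 45.0)


@dataclass
class CtRecord:
    gene: str
    condition: str
    replicate: int
    ct: float


@dataclass
class RelativeExpression:
    gene: str
    condition: str
    reference_condition: str
    delta_ct: float
    delta_delta_ct: float
    fold: float


def delta_delta_ct(
    records: pd.DataFrame,
    target_gene: str,
    ref_gene: str,
    reference_condition: str,
) -> list[RelativeExpression]:
    """ddCt relative expression of ``target_gene`` per condition.

    ``records`` is a long table with columns (gene, condition, replicate, ct).
    """
    for col in ("gene", "condition", "ct"):
        if col not in records.columns:
            raise ValueError(f"Ct table missing column {col!r}")
    bad = records[(records["ct"] <= CT_RANGE[0]) | (records["ct"] > CT_RANGE[1])]
    if not bad.empty:
        raise ValueError(f"Ct values outside (0, 45]: {bad['ct'].tolist()[:5]}")

    conditions = list(dict.fromkeys(records["condition"]))
    if reference_condition not in conditions:
        raise ValueError(f"reference condition {reference_condition!r} not in data")
    mean_ct = records.groupby(["gene", "condition"])["ct"].mean()
    for cond in conditions:
        if (ref_gene, cond) not in mean_ct.index:
            raise ValueError(
                f"reference gene {ref_gene!r} not measured in condition {cond!r}"
            )
        if (target_gene, cond) not in mean_ct.index:
            raise ValueError(
                f"target gene {target_gene!r} not measured in condition {cond!r}"
            )
    d_ct = {
        cond: float(mean_ct[(target_gene, cond)] - mean_ct[(ref_gene, cond)])
        for cond in conditions
    }
    base = d_ct[reference_condition]
    return [
        RelativeExpression(
            gene=target_gene,
            condition=cond,
            reference_condition=reference_condition,
            delta_ct=d_ct[cond],
            delta_delta_ct=d_ct[cond] - base,
            fold=2.0 ** -(d_ct[cond] - base),
        )
        for cond in conditions
    ]
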