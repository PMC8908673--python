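"""Expression normalization, Classical/Basal-like subtyping, and correlation ranking.

The subtype classifier follows the Moffitt two-signature scheme as used for
patient-derived organoid (PDO) cohorts: expression values of the "Basal-like"
and "Classical" signature genes are z-scored per gene across samples, summed
per signature, and the total score (basal sum minus classical sum) decides the
label with a >= 0 boundary mapping to Basal-like.

Two estimator classes (:class:`QuantileNormalizer`,
:class:`MoffittSubtypeClassifier`) follow scikit-learn conventions and operate
on (n_samples, n_genes) arrays/DataFrames; the module-level functions wrap them
for the genes x samples :class:`ExpressionMatrix` container used throughout the
pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ExpressionMatrix",
    "GeneSignature",
    "SubtypeScore",
    "CorrelationRanking",
    "QuantileNormalizer",
    "MoffittSubtypeClassifier",
    "log2_quantile_normalize",
    "zscore_by_gene",
    "moffitt_classify",
    "correlate_with_score",
    "extract_top_bottom",
]

BASAL_LIKE = "Basal-like"
CLASSICAL = "Classical"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with an explicit normalization state.

    ``scale`` is one of ``raw`` (positive intensities), ``log2`` and
    ``log2_quantile``.
    """

    data: pd.DataFrame  # index = gene ids, columns = sample ids
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log2", "log2_quantile"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes[:5]}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class GeneSignature:
    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} contains duplicate genes")


@dataclass
class SubtypeScore:
    sample_id: str
    z_basal_sum: float
    z_classical_sum: float
    total_score: float
    label: str
    n_genes_used: dict[str, int] = field(default_factory=dict)


@dataclass
class CorrelationRanking:
    """Genes ranked by Pearson correlation with a per-sample score.

    ``entries`` is sorted by r descending, ties broken by gene id ascending.
    ``n_excluded`` counts genes dropped because r was undefined (zero variance
    or missing values).
    """

    entries: list[tuple[str, float, int]]  # (gene_id, r, rank starting at 1)
    score_name: str = "score"
    n_excluded: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["gene_id", "pearson_r", "rank"])


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def _quantile_map_to_reference(X: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Map every column of ``X`` onto the sorted ``reference`` distribution.

    Ties receive the mean of the reference values at the ranks the tie group
    occupies (the preprocessCore/limma convention).
    """
    n, m = X.shape
    out = np.empty((n, m), dtype=float)
    for j in range(m):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        sorted_vals = col[order]
        mapped = reference.copy()
        # average reference values over runs of tied input values
        i = 0
        while i < n:
            k = i + 1
            while k < n and sorted_vals[k] == sorted_vals[i]:
                k += 1
            if k - i > 1:
                mapped[i:k] = reference[i:k].mean()
            i = k
        out[order, j] = mapped
    return out


def quantile_normalize_columns(X: np.ndarray) -> np.ndarray:
    """Quantile-normalize the columns of ``X`` against their own mean-of-sorted
    reference distribution. Idempotent on its own output."""
    X = np.asarray(X, dtype=float)
    reference = np.sort(X, axis=0).mean(axis=1)
    return _quantile_map_to_reference(X, reference)


class QuantileNormalizer(TransformerMixin, BaseEstimator):
    """Quantile normalization as a scikit-learn transformer.

    ``fit`` learns the reference distribution (mean of the per-sample sorted
    value vectors over the fitted cohort); ``transform`` maps each sample (row)
    onto it. After transforming the data it was fitted on, every row holds the
    identical sorted multiset of values.
    """

    def fit(self, X, y=None):
        X = self._as_array(X)
        if X.ndim != 2 or X.shape[0] < 1:
            raise ValueError("expected a 2-D matrix with at least one sample")
        self.n_features_in_ = X.shape[1]
        self.reference_distribution_ = np.sort(X, axis=1).mean(axis=0)
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_distribution_")
        X = self._as_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        # rows are samples here; the helper works column-wise
        return _quantile_map_to_reference(X.T, self.reference_distribution_).T

    @staticmethod
    def _as_array(X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy()
        X = np.asarray(X, dtype=float)
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite values")
        return X


def log2_quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Log2-transform raw intensities and quantile-normalize across samples."""
    if m.scale != "raw":
        raise ValueError(
            f"input is already on scale {m.scale!r}; expected raw intensities"
        )
    vals = m.values
    if (vals <= 0).any():
        gi, sj = np.argwhere(vals <= 0)[0]
        raise ValueError(
            "non-positive intensity at gene "
            f"{m.gene_ids[gi]!r}, sample {m.sample_ids[sj]!r}"
        )
    log2 = np.log2(vals)
    norm = quantile_normalize_columns(log2)
    return ExpressionMatrix(
        data=pd.DataFrame(norm, index=m.data.index, columns=m.data.columns),
        scale="log2_quantile",
    )


# ---------------------------------------------------------------------------
# z-scores and subtype classification
# ---------------------------------------------------------------------------

def zscore_by_gene(m: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene z-score across samples (SD with n-1 denominator).

    Zero-variance genes yield an all-zero row and a warning.
    """
    if m.scale not in ("log2", "log2_quantile"):
        raise ValueError("z-scores are computed on log2 data; normalize first")
    if len(m.sample_ids) < 2:
        raise ValueError("need at least 2 samples for z-scores")
    vals = m.values
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance gene(s) set to z=0", stacklevel=2
        )
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (vals - mean) / safe_sd
    z[flat, :] = 0.0
    return pd.DataFrame(z, index=m.data.index, columns=m.data.columns)


class MoffittSubtypeClassifier(BaseEstimator):
    """Classical vs Basal-like subtype caller from two gene signatures.

    Parameters
    ----------
    basal_genes, classical_genes : list of str
        Signature gene ids. Genes absent from the data are dropped (and
        recorded in ``missing_genes_``); a signature with no matched gene is
        an error.

    ``fit`` expects a samples x genes DataFrame of log2 expression; it learns
    per-gene means/SDs over the fitted cohort so that ``predict`` /
    ``decision_function`` can score new samples on the same axis. The decision
    function is sum(z over basal genes) - sum(z over classical genes); a value
    >= 0 maps to "Basal-like".
    """

    def __init__(self, basal_genes=None, classical_genes=None):
        self.basal_genes = basal_genes
        self.classical_genes = classical_genes

    def fit(self, X: pd.DataFrame, y=None):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a samples x genes DataFrame with gene names")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 samples")
        sigs = {
            "basal": list(self.basal_genes or []),
            "classical": list(self.classical_genes or []),
        }
        present: dict[str, list[str]] = {}
        self.missing_genes_ = {}
        for name, genes in sigs.items():
            if not genes:
                raise ValueError(f"{name} signature is empty")
            hit = [g for g in genes if g in X.columns]
            if not hit:
                raise ValueError(f"no {name} signature gene found in the data")
            present[name] = hit
            self.missing_genes_[name] = sorted(set(genes) - set(hit))
        self.basal_genes_ = present["basal"]
        self.classical_genes_ = present["classical"]
        used = self.basal_genes_ + self.classical_genes_
        sub = X[used].to_numpy(dtype=float)
        self.gene_index_ = used
        self.mean_ = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=1)
        self.scale_ = np.where(sd == 0, 1.0, sd)
        self.zero_variance_ = sd == 0
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array([CLASSICAL, BASAL_LIKE])
        # transductive outputs for the fitted cohort
        self.scores_ = self._score_frame(X)
        self.labels_ = self.scores_["label"]
        return self

    def _score_frame(self, X: pd.DataFrame) -> pd.DataFrame:
        z = (X[self.gene_index_].to_numpy(dtype=float) - self.mean_) / self.scale_
        z[:, self.zero_variance_] = 0.0
        nb = len(self.basal_genes_)
        zb = z[:, :nb].sum(axis=1)
        zc = z[:, nb:].sum(axis=1)
        total = zb - zc
        return pd.DataFrame(
            {
                "z_basal_sum": zb,
                "z_classical_sum": zc,
                "total_score": total,
                "label": np.where(total >= 0, BASAL_LIKE, CLASSICAL),
            },
            index=X.index,
        )

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "mean_")
        return self._score_frame(X)["total_score"].to_numpy()

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "mean_")
        return self._score_frame(X)["label"].to_numpy()

    def fit_predict(self, X: pd.DataFrame, y=None) -> np.ndarray:
        return self.fit(X).labels_.to_numpy()


def moffitt_classify(
    m: ExpressionMatrix, basal: GeneSignature, classical: GeneSignature
) -> list[SubtypeScore]:
    """Score and label every sample of ``m`` with the two-signature scheme."""
    clf = MoffittSubtypeClassifier(
        basal_genes=basal.genes, classical_genes=classical.genes
    ).fit(m.data.T)
    n_used = {"basal": len(clf.basal_genes_), "classical": len(clf.classical_genes_)}
    for name, missing in clf.missing_genes_.items():
        if missing:
            warnings.warn(
                f"{len(missing)} {name} signature gene(s) absent from data",
                stacklevel=2,
            )
    return [
        SubtypeScore(
            sample_id=str(sid),
            z_basal_sum=float(row.z_basal_sum),
            z_classical_sum=float(row.z_classical_sum),
            total_score=float(row.total_score),
            label=str(row.label),
            n_genes_used=dict(n_used),
        )
        for sid, row in clf.scores_.iterrows()
    ]


# ---------------------------------------------------------------------------
# correlation ranking
# ---------------------------------------------------------------------------

def correlate_with_score(m: ExpressionMatrix, scores) -> CorrelationRanking:
    """Pearson r of every gene's expression profile against a per-sample score.

    ``scores`` is a mapping or Series covering every sample of ``m``. Genes
    with zero variance or missing values are excluded and counted in
    ``n_excluded``. Entries are sorted by r descending, gene id ascending.
    """
    s = pd.Series(scores)
    missing = [sid for sid in m.sample_ids if sid not in s.index]
    if missing:
        raise ValueError(f"scores missing for samples: {missing}")
    if len(m.sample_ids) < 3:
        raise ValueError("need at least 3 samples for correlation ranking")
    y = s.loc[m.sample_ids].to_numpy(dtype=float)
    X = m.values
    yc = y - y.mean()
    ys = np.sqrt((yc**2).sum())
    if ys == 0:
        raise ValueError("score vector has zero variance")
    Xc = X - X.mean(axis=1, keepdims=True)
    xs = np.sqrt((Xc**2).sum(axis=1))
    ok = (xs > 0) & np.isfinite(X).all(axis=1)
    r = np.full(X.shape[0], np.nan)
    r[ok] = np.clip((Xc[ok] @ yc) / (xs[ok] * ys), -1.0, 1.0)
    frame = pd.DataFrame({"gene_id": m.gene_ids, "r": r}).loc[ok]
    frame = frame.sort_values(["r", "gene_id"], ascending=[False, True])
    entries = [
        (str(g), float(rv), i + 1)
        for i, (g, rv) in enumerate(zip(frame["gene_id"], frame["r"]))
    ]
    name = s.name if s.name is not None else "score"
    return CorrelationRanking(
        entries=entries, score_name=str(name), n_excluded=int((~ok).sum())
    )


def extract_top_bottom(
    rank: CorrelationRanking, k: int = 1000
) -> tuple[list[str], list[str]]:
    """Top-k and bottom-k correlated genes (disjoint by construction).

    The top list is the head of the ranking; the bottom list is the tail,
    returned in ascending-r order.
    """
    n = len(rank.entries)
    if k < 1 or 2 * k > n:
        raise ValueError(f"k={k} must satisfy 1 <= k <= n_ranked/2 (n_ranked={n})")
    top = [g for g, _, _ in rank.entries[:k]]
    tail = sorted(rank.entries[-k:], key=lambda e: (e[1], e[0]))
    bottom = [g for g, _, _ in tail]
    return top, bottom
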