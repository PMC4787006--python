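"""Expression-share accounting, normalization and morph-biased DE calling.

The differential-expression test is a documented negative-binomial Wald
test, not a call to an external DE package: per-contig dispersions are
estimated by the method of moments on normalized counts and shrunk 50/50
toward a parametric mean-dispersion trend alpha(mu) = a0 + a1/mu fitted by
least squares.  Normalization uses the median-of-ratios size factors.
The bias classification applies the published thresholds: a contig is
morph-biased at adjusted p < 0.01 with |log2 fold change| > 1, unbiased at
adjusted p > 0.05 with |log2 fold change| < 1, and ambiguous otherwise.
Orientation follows the convention positive log2fc = higher in the
root-feeding morph (radicicoles / gallicoles).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import (
    DegenerateLibraryError,
    DesignError,
    NormalizationError,
    ParameterError,
    UnknownIdError,
)

__all__ = [
    "CountMatrix",
    "ShareTable",
    "BIAS_CLASSES",
    "compute_shares",
    "family_share",
    "size_factors",
    "bh_adjust",
    "nb_de_test",
    "classify_bias",
]

BIAS_CLASSES = ("RA_biased", "GA_biased", "unbiased", "ambiguous")

MIN_DISPERSION = 1e-8
LOG2FC_PSEUDOCOUNT = 0.5


@dataclass
class CountMatrix:
    """Contig x library integer read counts plus library metadata.

    ``counts``: DataFrame indexed by contig id, one column per library.
    ``design``: DataFrame indexed by library name with columns ``condition``
    and ``replicate``.
    """

    counts: pd.DataFrame
    design: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].unique()
            raise ParameterError(f"duplicate contig ids: {list(dupes)[:5]}")
        if (self.counts.to_numpy() < 0).any():
            raise ParameterError("counts must be non-negative")
        totals = self.counts.sum(axis=0)
        if (totals == 0).any():
            bad = list(totals.index[totals == 0])
            raise DegenerateLibraryError(f"libraries with zero total counts: {bad}")
        if self.design is None:
            self.design = pd.DataFrame(
                {"condition": self.counts.columns, "replicate": 1},
                index=self.counts.columns,
            )
        missing = set(self.counts.columns) - set(self.design.index)
        if missing:
            raise ParameterError(f"libraries missing from design: {sorted(missing)}")
        self.design = self.design.loc[list(self.counts.columns)]

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    def condition_libraries(self, condition: str) -> list[str]:
        mask = self.design["condition"] == condition
        return list(self.design.index[mask])


@dataclass
class ShareTable:
    """Percent-of-mapped-reads shares per library and per condition."""

    per_library: pd.DataFrame
    per_condition: pd.DataFrame


def compute_shares(cm: CountMatrix) -> ShareTable:
    """Share = 100 x count / library total; condition = mean over replicates."""
    totals = cm.counts.sum(axis=0)
    per_library = 100.0 * cm.counts / totals
    cond = per_library.T.groupby(cm.design["condition"]).mean().T
    return ShareTable(per_library=per_library, per_condition=cond)


def family_share(st: ShareTable, member_ids) -> pd.Series:
    """Summed per-condition shares of a gene family, to 2 decimals."""
    member_ids = list(member_ids)
    missing = set(member_ids) - set(st.per_condition.index)
    if missing:
        raise UnknownIdError(f"unknown family member ids: {sorted(missing)}")
    if not member_ids:
        return pd.Series(0.0, index=st.per_condition.columns).round(2)
    return st.per_condition.loc[member_ids].sum(axis=0).round(2)


def size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    For each contig with nonzero counts in every library, the ratio of its
    count to its across-library geometric mean is formed; the factor of a
    library is the median of these ratios.  Scale-equivariant and invariant
    to contig order.
    """
    counts = cm.counts.to_numpy(dtype=float)
    all_nonzero = (counts > 0).all(axis=1)
    if not all_nonzero.any():
        raise NormalizationError(
            "no contig has nonzero counts in every library; consider the "
            "share-based fallback (compute_shares) instead"
        )
    sub = counts[all_nonzero]
    log_geomean = np.log(sub).mean(axis=1, keepdims=True)
    ratios = np.exp(np.log(sub) - log_geomean)
    return pd.Series(np.median(ratios, axis=0), index=cm.counts.columns, name="size_factor")


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_bias(
    padj: float,
    log2fc: float,
    p_biased: float = 0.01,
    lfc_min: float = 1.0,
    p_unbiased: float = 0.05,
) -> str:
    """Published bias classes with strict inequalities.

    ``RA_biased`` (higher in the numerator condition) at padj < p_biased and
    log2fc > lfc_min; ``GA_biased`` at padj < p_biased and log2fc < -lfc_min;
    ``unbiased`` at padj > p_unbiased and |log2fc| < lfc_min; everything
    else, including untested contigs (padj = NaN), is ``ambiguous``.
    """
    if padj is None or not np.isfinite(padj):
        return "ambiguous"
    if padj < p_biased and log2fc > lfc_min:
        return "RA_biased"
    if padj < p_biased and log2fc < -lfc_min:
        return "GA_biased"
    if padj > p_unbiased and abs(log2fc) < lfc_min:
        return "unbiased"
    return "ambiguous"


def _dispersion_trend(base_mean: np.ndarray, alpha_mom: np.ndarray) -> np.ndarray:
    """Least-squares fit of alpha = a0 + a1/mu, evaluated at each mu."""
    ok = base_mean > 0
    x = 1.0 / base_mean[ok]
    design = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(design, alpha_mom[ok], rcond=None)
    with np.errstate(divide="ignore"):
        fitted = coef[0] + coef[1] / base_mean
    return np.maximum(fitted, MIN_DISPERSION)


def nb_de_test(
    cm: CountMatrix,
    numerator: str = "RA",
    denominator: str = "GA",
    p_biased: float = 0.01,
    lfc_min: float = 1.0,
    p_unbiased: float = 0.05,
) -> pd.DataFrame:
    """Negative-binomial Wald test between two conditions.

    Returns one row per contig with columns ``base_mean``, ``log2fc``
    (log2 of numerator over denominator normalized means, pseudo-count
    0.5), ``p``, ``padj`` (BH over tested contigs), ``bias`` and ``tested``.
    Contigs with all-zero counts across the compared libraries are excluded
    from testing and reported with bias ``ambiguous`` and padj NaN.
    """
    libs_den = cm.condition_libraries(denominator)
    libs_num = cm.condition_libraries(numerator)
    if len(libs_den) < 2 or len(libs_num) < 2:
        raise DesignError(
            f"need >=2 replicates per condition, got {denominator}:{len(libs_den)} "
            f"{numerator}:{len(libs_num)}"
        )
    libs = libs_den + libs_num
    sub = CountMatrix(cm.counts[libs].copy(), cm.design.loc[libs].copy())
    sf = size_factors(sub)
    norm = sub.counts.to_numpy(dtype=float) / sf.to_numpy()

    n_den, n_num = len(libs_den), len(libs_num)
    x_den, x_num = norm[:, :n_den], norm[:, n_den:]
    mean_den = x_den.mean(axis=1)
    mean_num = x_num.mean(axis=1)
    base_mean = norm.mean(axis=1)
    tested = base_mean > 0

    # pooled within-condition residual variance (method of moments)
    resid = np.concatenate(
        [x_den - mean_den[:, None], x_num - mean_num[:, None]], axis=1
    )
    var = (resid**2).sum(axis=1) / (n_den + n_num - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = np.where(
            base_mean > 0, (var - base_mean) / base_mean**2, MIN_DISPERSION
        )
    alpha_mom = np.clip(alpha_mom, MIN_DISPERSION, None)
    trend = _dispersion_trend(base_mean[tested], alpha_mom[tested])
    alpha = np.full(len(base_mean), MIN_DISPERSION)
    alpha[tested] = 0.5 * alpha_mom[tested] + 0.5 * trend

    log2fc = np.log2(mean_num + LOG2FC_PSEUDOCOUNT) - np.log2(
        mean_den + LOG2FC_PSEUDOCOUNT
    )
    ln2_sq = np.log(2.0) ** 2

    def _var_log2_mean(m: np.ndarray, n: int) -> np.ndarray:
        return (m + alpha * m**2) / n / ((m + LOG2FC_PSEUDOCOUNT) ** 2 * ln2_sq)

    se = np.sqrt(_var_log2_mean(mean_den, n_den) + _var_log2_mean(mean_num, n_num))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.minimum(p, 1.0)

    padj = np.full(len(p), np.nan)
    if tested.any():
        padj[tested] = bh_adjust(p[tested])

    bias = np.array(
        [
            classify_bias(pa, fc, p_biased, lfc_min, p_unbiased) if t else "ambiguous"
            for pa, fc, t in zip(padj, log2fc, tested)
        ],
        dtype=object,
    )
    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "p": np.where(tested, p, np.nan),
            "padj": padj,
            "bias": bias,
            "tested": tested,
        },
        index=cm.counts.index.rename("contig_id"),
    )
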