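"""Standard-curve qPCR quantification and RNAseq/qPCR agreement.

Implements the standard-curve method of relative quantification: an
ordinary least-squares fit of Cq on log10(quantity) over a serial-dilution
series per gene (amplification efficiency = 10^(-1/slope) - 1), conversion
of sample Cq values to quantities, normalization of each target by the
geometric mean of two invariant reference genes, and the correlation of
log2 fold changes between qPCR and RNAseq.

Technical replicates are collapsed by the arithmetic mean of *quantities*
(not of Cq) before normalization, and condition-level fold changes are
computed from biological-replicate means with the log taken last; both
choices are configurable conventions documented here because the procedure
itself does not dictate them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError, InsufficientDataError, InvalidCurveError, NormalizationError

__all__ = [
    "StandardCurve",
    "fit_standard_curve",
    "quantify",
    "normalize_relative",
    "relative_expression",
    "MethodCorrelation",
    "method_correlation",
]


@dataclass(frozen=True)
class StandardCurve:
    """Dilution-series regression of Cq on log10(quantity) for one gene."""

    slope: float
    intercept: float
    efficiency: float
    r_squared: float
    gene: str = ""


def fit_standard_curve(log10_quantity, cq, *, gene: str = "") -> StandardCurve:
    """OLS fit of Cq on log10(quantity) over a serial dilution series.

    Requires at least 3 distinct dilution points.  The amplification
    efficiency is 10^(-1/slope) - 1 (1.0 for a perfect doubling per cycle,
    i.e. slope -1/log10(2) ~ -3.3219).
    """
    x = np.asarray(log10_quantity, dtype=float)
    y = np.asarray(cq, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise FitError("log10_quantity and cq must be matching 1-D arrays")
    if len(np.unique(x)) < 3:
        raise FitError("standard curve needs >=3 distinct dilution points")
    res = stats.linregress(x, y)
    if res.slope == 0:
        raise FitError("degenerate standard curve: zero slope")
    efficiency = 10.0 ** (-1.0 / res.slope) - 1.0
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        efficiency=float(efficiency),
        r_squared=float(res.rvalue) ** 2,
        gene=gene,
    )


def quantify(cq, curve: StandardCurve):
    """Cq -> quantity (arbitrary units): 10^((Cq - intercept) / slope)."""
    if curve.slope >= 0:
        raise InvalidCurveError(
            f"standard curve for {curve.gene or 'gene'} has non-negative slope"
        )
    return 10.0 ** ((np.asarray(cq, dtype=float) - curve.intercept) / curve.slope)


def normalize_relative(target, ref1, ref2):
    """Target quantity over the geometric mean of two reference quantities.

    Operates per matched sample (e.g. per biological replicate, technical
    replicates already averaged).  Invariant to swapping the references.
    """
    t = np.asarray(target, dtype=float)
    r1 = np.asarray(ref1, dtype=float)
    r2 = np.asarray(ref2, dtype=float)
    if not (t.shape == r1.shape == r2.shape):
        raise NormalizationError("target and reference arrays must align")
    if np.any(r1 <= 0) or np.any(r2 <= 0):
        raise NormalizationError("reference quantities must be positive")
    return t / np.sqrt(r1 * r2)


def relative_expression(
    cq: pd.DataFrame,
    curves: dict[str, StandardCurve],
    reference_genes: tuple[str, str],
) -> pd.DataFrame:
    """Per-condition normalized expression of each target gene.

    ``cq`` is tidy with columns gene, condition, bio_rep, tech_rep, cq.
    Pipeline: Cq -> quantity via the gene's standard curve; arithmetic mean
    over technical replicates; division by the geometric mean of the two
    reference-gene quantities per (condition, bio_rep); arithmetic mean
    over biological replicates per condition.  Returns a DataFrame indexed
    by target gene with one column per condition.
    """
    ref1, ref2 = reference_genes
    missing = {ref1, ref2} - set(cq["gene"])
    if missing:
        raise NormalizationError(f"reference genes absent from Cq table: {sorted(missing)}")
    work = cq.copy()
    work["quantity"] = [
        float(quantify(row.cq, curves[row.gene])) for row in work.itertuples()
    ]
    per_bio = (
        work.groupby(["gene", "condition", "bio_rep"])["quantity"].mean().reset_index()
    )
    wide = per_bio.pivot_table(
        index=["condition", "bio_rep"], columns="gene", values="quantity"
    )
    targets = [g for g in wide.columns if g not in (ref1, ref2)]
    normed = wide[targets].to_numpy() / np.sqrt(
        wide[ref1].to_numpy() * wide[ref2].to_numpy()
    )[:, None]
    if np.any(~np.isfinite(normed)):
        raise NormalizationError("non-finite normalized quantity (missing reference?)")
    normed_df = pd.DataFrame(normed, index=wide.index, columns=targets)
    out = normed_df.groupby(level="condition").mean().T
    out.index.name = "gene"
    return out


@dataclass(frozen=True)
class MethodCorrelation:
    genes: tuple
    rnaseq_log2fc: tuple
    qpcr_log2fc: tuple
    pearson_r: float
    slope: float
    intercept: float


def method_correlation(
    rnaseq_log2fc: pd.Series,
    qpcr_condition_means: pd.DataFrame,
    numerator: str = "RA",
    denominator: str = "GA",
) -> MethodCorrelation:
    """Pearson agreement between RNAseq and qPCR log2 fold changes.

    ``rnaseq_log2fc`` maps gene -> RNAseq log2fc; ``qpcr_condition_means``
    is the output of :func:`relative_expression`.  The qPCR log2fc is
    log2(numerator condition mean / denominator condition mean).  At least
    3 genes must be shared.
    """
    genes = sorted(set(rnaseq_log2fc.index) & set(qpcr_condition_means.index))
    if len(genes) < 3:
        raise InsufficientDataError(f"only {len(genes)} genes shared between methods")
    qpcr_fc = np.log2(
        qpcr_condition_means.loc[genes, numerator].to_numpy()
        / qpcr_condition_means.loc[genes, denominator].to_numpy()
    )
    rna_fc = rnaseq_log2fc.loc[genes].to_numpy(dtype=float)
    r, _ = stats.pearsonr(rna_fc, qpcr_fc)
    reg = stats.linregress(rna_fc, qpcr_fc)
    return MethodCorrelation(
        genes=tuple(genes),
        rnaseq_log2fc=tuple(rna_fc),
        qpcr_log2fc=tuple(qpcr_fc),
        pearson_r=float(r),
        slope=float(reg.slope),
        intercept=float(reg.intercept),
    )
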