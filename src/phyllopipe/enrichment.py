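"""GO-term enrichment between two gene lists by Fisher's exact test.

Compares the annotation composition of two disjoint contig lists (e.g.
RA-biased vs unbiased), one 2x2 table per GO term, two-sided Fisher exact
p-values, and Benjamini-Hochberg FDR across all tested terms with the
published cutoff of 0.05.  The universe is restricted to annotated contigs
(only a minority of de novo contigs carry GO terms); unannotated contigs
are dropped from both lists with a logged count.  Annotations are tested
as given — no ancestor propagation up the GO graph.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import DegenerateTableError, ParameterError
from .expression import bh_adjust

__all__ = ["build_tables", "fisher_exact", "enrich", "hypergeom_pmf"]

logger = logging.getLogger(__name__)

GO_TERM_RE = re.compile(r"^GO:\d{7}$")

# relative slack on the "as or more extreme" comparison of the two-sided test
_REL_TOL = 1e-7


def _check_go_term(term: str) -> str:
    if not GO_TERM_RE.match(term):
        raise ParameterError(f"malformed GO term id: {term!r}")
    return term


def build_tables(listA, listB, ann: dict[str, set]) -> pd.DataFrame:
    """Per-term 2x2 counts between two disjoint contig lists.

    Rows of each table are (list A, list B), columns (has term, lacks term):
    ``a`` = A with term, ``b`` = A without, ``c`` = B with, ``d`` = B
    without.  Contigs absent from ``ann`` (or annotated with no terms) are
    excluded from both lists.  One table per term seen in either list.
    """
    setA, setB = set(listA), set(listB)
    if not setA or not setB:
        raise ParameterError("both lists must be nonempty")
    overlap = setA & setB
    if overlap:
        raise ParameterError(f"lists overlap on {len(overlap)} contigs")
    annA = sorted(c for c in setA if ann.get(c))
    annB = sorted(c for c in setB if ann.get(c))
    dropped = (len(setA) - len(annA)) + (len(setB) - len(annB))
    if dropped:
        logger.info("build_tables: dropped %d unannotated contigs", dropped)
    nA, nB = len(annA), len(annB)
    if nA == 0 or nB == 0:
        raise ParameterError("a list has no annotated contigs")
    terms: dict[str, list[int]] = {}
    for contig in annA:
        for term in ann[contig]:
            terms.setdefault(_check_go_term(term), [0, 0])[0] += 1
    for contig in annB:
        for term in ann[contig]:
            terms.setdefault(_check_go_term(term), [0, 0])[1] += 1
    rows = [
        {"term": t, "a": a, "b": nA - a, "c": c, "d": nB - c}
        for t, (a, c) in sorted(terms.items())
    ]
    return pd.DataFrame(rows, columns=["term", "a", "b", "c", "d"])


def hypergeom_pmf(support: np.ndarray, N: int, K: int, n: int) -> np.ndarray:
    """P(X = k) for X ~ Hypergeometric(N, K, n), vectorized over ``support``."""
    k = np.asarray(support, dtype=float)

    def _logC(n_, k_):
        return gammaln(n_ + 1) - gammaln(k_ + 1) - gammaln(n_ - k_ + 1)

    return np.exp(_logC(K, k) + _logC(N - K, n - k) - _logC(N, n))


def fisher_exact(table, *, alternative: str = "two-sided") -> float:
    """Fisher's exact test p-value on a 2x2 table [[a, b], [c, d]].

    The two-sided p sums hypergeometric probabilities of all tables (same
    margins) whose probability does not exceed that of the observed table,
    with a relative slack of 1e-7 on the comparison.  One-sided
    alternatives ("greater"/"less") refer to the observed ``a`` cell.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ParameterError("table must be 2x2")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        raise ParameterError("table entries must be non-negative integers")
    a, b, c, d = (int(x) for x in arr.ravel())
    N = a + b + c + d
    K = a + b  # row-1 margin
    n = a + c  # column-1 margin
    if K == 0 or K == N or n == 0 or n == N:
        raise DegenerateTableError(f"table has a zero margin: {[[a, b], [c, d]]}")
    lo, hi = max(0, n - (N - K)), min(K, n)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom_pmf(support, N, K, n)
    p_obs = pmf[a - lo]
    if alternative == "two-sided":
        p = float(pmf[pmf <= p_obs * (1.0 + _REL_TOL)].sum())
    elif alternative == "greater":
        p = float(pmf[support >= a].sum())
    elif alternative == "less":
        p = float(pmf[support <= a].sum())
    else:
        raise ParameterError(f"unknown alternative {alternative!r}")
    return min(p, 1.0)


def enrich(
    listA,
    listB,
    ann: dict[str, set],
    fdr: float = 0.05,
    *,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Per-term enrichment records between two lists, BH-FDR flagged.

    Returns a DataFrame sorted by (q, p, term) with the 2x2 counts, the
    sample odds ratio, the Fisher p, the BH q and ``significant = q < fdr``.
    """
    tables = build_tables(listA, listB, ann)
    if tables.empty:
        return tables.assign(odds_ratio=[], p=[], q=[], significant=[])
    pvals = [
        fisher_exact([[r.a, r.b], [r.c, r.d]], alternative=alternative)
        for r in tables.itertuples()
    ]
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = (tables["a"] * tables["d"]) / (tables["b"] * tables["c"])
    out = tables.assign(odds_ratio=odds, p=pvals, q=bh_adjust(pvals))
    out["significant"] = out["q"] < fdr
    return out.sort_values(["q", "p", "term"]).reset_index(drop=True)
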