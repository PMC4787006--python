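"""Independent reference implementations used only as test oracles.

Each oracle recomputes a quantity by a different route from the package
implementation: brute-force dynamic programming, explicit enumeration, or
an external library primitive.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Seq import Seq
from scipy.stats import hypergeom


def ungapped_local_score(a: str, b: str, match: int = 1, mismatch: int = -2) -> int:
    """Best ungapped local alignment score by full O(nm) dynamic programming.

    Row-by-row recurrence H[i, j] = max(0, H[i-1, j-1] + s(i, j)): with gaps
    prohibited this equals the Smith-Waterman optimum, scanning every
    diagonal rather than only seeded ones.
    """
    arr_a = np.frombuffer(a.encode(), dtype=np.uint8)
    arr_b = np.frombuffer(b.encode(), dtype=np.uint8)
    prev = np.zeros(len(arr_b) + 1, dtype=np.int64)
    best = 0
    for ca in arr_a:
        sc = np.where((arr_b == ca) & (arr_b != ord("N")), match, mismatch)
        curr = np.zeros_like(prev)
        curr[1:] = np.maximum(0, prev[:-1] + sc)
        best = max(best, int(curr.max()))
        prev = curr
    return best


def n50_bruteforce(lengths) -> int:
    """N50 by scanning lengths from largest: first L whose cumulative sum of
    lengths >= L reaches half the total."""
    lengths = sorted(lengths, reverse=True)
    total = sum(lengths)
    running = 0
    for L in lengths:
        running += L
        if 2 * running >= total:
            return L
    raise AssertionError("unreachable")


def bh_bruteforce(pvals) -> np.ndarray:
    """BH adjusted p-values via the explicit min-over-suffix formula."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for rank, idx in enumerate(order, start=1):
        candidates = [
            p[order[j - 1]] * m / j for j in range(rank, m + 1)
        ]
        adj[idx] = min(1.0, min(candidates))
    return adj


def fisher_twosided_enum(a: int, b: int, c: int, d: int, rel_tol: float = 1e-7) -> float:
    """Two-sided Fisher p by explicit hypergeometric enumeration (scipy pmf)."""
    N, K, n = a + b + c + d, a + b, a + c
    lo, hi = max(0, n - (N - K)), min(K, n)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, N, K, n)
    return float(min(1.0, pmf[pmf <= pmf[a - lo] * (1 + rel_tol)].sum()))


# ---------------------------------------------------------------- NG86 oracle

_STOPS = {"TAA", "TAG", "TGA"}


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def syn_sites_oracle(codon: str) -> float:
    syn = 0
    for pos, base in enumerate(codon):
        for alt in "ACGT":
            if alt == base:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if _translate(mutant) == _translate(codon) and _translate(codon) != "*":
                syn += 1
    return syn / 3.0


def pathway_counts_oracle(c1: str, c2: str) -> tuple[float, float]:
    """Equal-weight average of (syn, nonsyn) steps over minimal pathways,
    excluding pathways through stop codons (all-pathway fallback)."""
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0

    def walk(current: str, remaining: tuple[int, ...]):
        if not remaining:
            return [([], False)]
        results = []
        for k, pos in enumerate(remaining):
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            step_syn = _translate(current) == _translate(nxt)
            stop_hit = nxt in _STOPS and nxt != c2
            rest = remaining[:k] + remaining[k + 1 :]
            for steps, blocked in walk(nxt, rest):
                results.append(([step_syn] + steps, blocked or stop_hit))
        return results

    paths = walk(c1, tuple(positions))
    valid = [steps for steps, blocked in paths if not blocked]
    if not valid:
        valid = [steps for steps, _ in paths]
    syn = sum(sum(steps) for steps in valid) / len(valid)
    nonsyn = sum(len(steps) - sum(steps) for steps in valid) / len(valid)
    return float(syn), float(nonsyn)


def ng86_oracle(seq_a: str, seq_b: str):
    """Full NG86 estimate (S, N, Sd, Nd, dS, dN) by the oracle routines."""
    codons_a = [seq_a[i : i + 3] for i in range(0, len(seq_a), 3)]
    codons_b = [seq_b[i : i + 3] for i in range(0, len(seq_b), 3)]
    S = (sum(map(syn_sites_oracle, codons_a)) + sum(map(syn_sites_oracle, codons_b))) / 2
    N = 3 * len(codons_a) - S
    Sd = Nd = 0.0
    for c1, c2 in zip(codons_a, codons_b):
        s, n = pathway_counts_oracle(c1, c2)
        Sd += s
        Nd += n

    def jc(p):
        arg = 1 - 4 * p / 3
        return float("nan") if arg <= 0 else -0.75 * np.log(arg)

    pS = Sd / S if S else 0.0
    pN = Nd / N if N else 0.0
    return S, N, Sd, Nd, jc(pS), jc(pN)


def all_sense_codons() -> list[str]:
    return [
        "".join(c)
        for c in itertools.product("TCAG", repeat=3)
        if "".join(c) not in _STOPS
    ]
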