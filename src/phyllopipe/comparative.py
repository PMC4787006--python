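"""Cross-species gene-family bookkeeping, codon composition and dN/dS.

Holds four loosely coupled analyses that all operate downstream of the
assembled transcriptome:

* family categories between two species (many-to-many, many-to-one,
  one-to-one, species-specific families and singletons) from a
  gene -> family -> species membership table;
* a simplified longest-ORF finder (six-frame, ATG..stop, complete ORFs
  only) standing in for an HMM-based CDS predictor;
* pooled GC percentage at each codon position of a CDS set;
* Nei-Gojobori (1986) counting of synonymous/non-synonymous substitution
  rates with Jukes-Cantor correction, plus a rank-sum comparison of dN
  across expression-bias classes.

NG86 replaces maximum-likelihood codon models here deliberately: at the
phylogenetic distances involved dS is saturated and only the ordinal
behaviour of dN is interpreted, which counting methods capture.  Pairs
with dS > 3 are flagged saturated.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    EmptyInputError,
    FrameError,
    InsufficientDataError,
    ParameterError,
    SequenceFormatError,
)
from .expression import bh_adjust

__all__ = [
    "GENETIC_CODE",
    "FAMILY_CATEGORIES",
    "classify_family",
    "family_counts",
    "Orf",
    "find_orfs",
    "codon_gc",
    "RateEstimate",
    "ng86",
    "compare_rates",
]

# Standard genetic code (NCBI translation table 1); the dict is the single
# configurable hook for alternative codes.
_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
GENETIC_CODE: dict[str, str] = {
    b1 + b2 + b3: _AA[16 * i + 4 * j + k]
    for i, b1 in enumerate(_BASES)
    for j, b2 in enumerate(_BASES)
    for k, b3 in enumerate(_BASES)
}
_STOPS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")

SATURATION_DS = 3.0

FAMILY_CATEGORIES = (
    "many_to_many",
    "many_A_to_one_B",
    "many_B_to_one_A",
    "one_to_one",
    "A_specific_family",
    "B_specific_family",
    "A_singleton",
    "B_singleton",
)


def classify_family(nA: int, nB: int) -> str:
    """Category of a gene family from its per-species gene counts."""
    if nA < 0 or nB < 0:
        raise ParameterError("gene counts must be non-negative")
    if nA == 0 and nB == 0:
        raise EmptyInputError("family with no genes in either species")
    if nA >= 2 and nB >= 2:
        return "many_to_many"
    if nA >= 2 and nB == 1:
        return "many_A_to_one_B"
    if nA == 1 and nB >= 2:
        return "many_B_to_one_A"
    if nA == 1 and nB == 1:
        return "one_to_one"
    if nA >= 2:
        return "A_specific_family"
    if nB >= 2:
        return "B_specific_family"
    return "A_singleton" if nA == 1 else "B_singleton"


def family_counts(
    fm: pd.DataFrame,
    *,
    species_a: str = "A",
    species_b: str = "B",
    singleton_marker: str = "-",
) -> pd.DataFrame:
    """Family and gene counts per homology category, with a totals row.

    ``fm`` needs columns ``gene_id``, ``family_id`` (``singleton_marker``
    for genes outside any family) and ``species``.  Gene totals per species
    are conserved: the category columns sum to the number of input genes.
    """
    required = {"gene_id", "family_id", "species"}
    if not required.issubset(fm.columns):
        raise ParameterError(f"membership table needs columns {sorted(required)}")
    bad = set(fm["species"]) - {species_a, species_b}
    if bad:
        raise ParameterError(f"unknown species labels: {sorted(bad)}")
    if fm["gene_id"].duplicated().any():
        raise ParameterError("a gene appears in more than one membership row")
    counts = {cat: {"n_families": 0, "genes_A": 0, "genes_B": 0} for cat in FAMILY_CATEGORIES}
    families = fm[fm["family_id"] != singleton_marker]
    for _, grp in families.groupby("family_id"):
        nA = int((grp["species"] == species_a).sum())
        nB = int((grp["species"] == species_b).sum())
        cat = classify_family(nA, nB)
        counts[cat]["n_families"] += 1
        counts[cat]["genes_A"] += nA
        counts[cat]["genes_B"] += nB
    singles = fm[fm["family_id"] == singleton_marker]
    for species, cat in ((species_a, "A_singleton"), (species_b, "B_singleton")):
        n = int((singles["species"] == species).sum())
        counts[cat]["n_families"] += n  # a singleton is its own trivial family
        counts[cat]["genes_A" if cat == "A_singleton" else "genes_B"] += n
    out = pd.DataFrame(counts).T.loc[list(FAMILY_CATEGORIES)]
    out.loc["total"] = out.sum(axis=0)
    out.index.name = "category"
    return out


@dataclass(frozen=True)
class Orf:
    """A complete open reading frame.

    ``start``/``end`` delimit the ORF span *including* the stop codon,
    0-based half-open, in the coordinates of the input sequence (for the
    minus strand: the region whose reverse complement is the ORF).  ``cds``
    excludes the stop codon.
    """

    strand: str
    frame: int
    start: int
    end: int
    cds: str


_RC = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def find_orfs(seq: str, min_codons: int = 100) -> Orf | None:
    """Longest complete ORF (ATG..stop) over six frames, or None.

    Only complete ORFs are reported (an ATG with an in-frame stop);
    5'-partial ORFs are deliberately excluded, a simplification relative to
    HMM-based predictors.  Ties break to the forward strand, then the
    lowest frame, then the leftmost start in the scanned orientation.
    """
    seq = seq.upper()
    if set(seq) - set("ACGTN"):
        raise SequenceFormatError("sequence contains non-IUPAC characters")
    L = len(seq)
    best = None  # (-n_codons, strand_rank, frame, scan_start)
    for strand_rank, (strand, scanned) in enumerate((("+", seq), ("-", _revcomp(seq)))):
        for frame in range(3):
            start = None
            for pos in range(frame, len(scanned) - 2, 3):
                codon = scanned[pos : pos + 3]
                if codon in _STOPS:
                    if start is not None:
                        n_codons = (pos - start) // 3
                        if n_codons >= min_codons:
                            key = (-n_codons, strand_rank, frame, start)
                            if best is None or key < best[0]:
                                best = (key, strand, frame, start, pos + 3, scanned)
                        start = None
                elif start is None and codon == "ATG":
                    start = pos
    if best is None:
        return None
    _, strand, frame, s, e, scanned = best
    cds = scanned[s : e - 3]
    if strand == "-":
        s, e = L - e, L - s
    return Orf(strand=strand, frame=frame, start=s, end=e, cds=cds)


def codon_gc(cds_set) -> tuple[float, float, float]:
    """Pooled GC percentage at codon positions 1-3 of a CDS collection.

    ``cds_set`` may be a mapping id -> sequence or an iterable of
    sequences.  Every sequence must have length divisible by 3; the error
    names the offending sequence.
    """
    items = cds_set.items() if hasattr(cds_set, "items") else enumerate(cds_set)
    gc = np.zeros(3, dtype=np.int64)
    n_codons = 0
    seen = False
    for name, cds in items:
        seen = True
        cds = cds.upper()
        if len(cds) % 3 != 0:
            raise FrameError(f"CDS {name!r} length {len(cds)} is not a multiple of 3")
        arr = np.frombuffer(cds.encode("ascii"), dtype=np.uint8).reshape(-1, 3)
        gc += ((arr == ord("G")) | (arr == ord("C"))).sum(axis=0)
        n_codons += arr.shape[0]
    if not seen or n_codons == 0:
        raise EmptyInputError("codon_gc requires at least one nonempty CDS")
    return tuple(100.0 * g / n_codons for g in gc)


@lru_cache(maxsize=None)
def _syn_fraction(codon: str) -> float:
    """Synonymous sites of a codon: per position, the fraction of the three
    single-nucleotide changes that preserve the amino acid.  Changes to a
    stop codon count as non-synonymous, so sites sum to 3 per codon."""
    aa = GENETIC_CODE[codon]
    syn = 0.0
    for pos in range(3):
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if GENETIC_CODE[mutant] == aa:
                syn += 1.0
    return syn / 3.0


@lru_cache(maxsize=None)
def _pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) differences between two codons,
    averaged over equally weighted minimal mutational pathways.

    Pathways passing through a stop codon are excluded from the average;
    if every pathway is blocked, all pathways are used as a fallback."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        current = c1
        sd = nd = 0.0
        blocked = False
        for pos in order:
            mutant = current[:pos] + c2[pos] + current[pos + 1 :]
            if mutant in _STOPS and mutant != c2:
                blocked = True
            if GENETIC_CODE[current] == GENETIC_CODE[mutant]:
                sd += 1.0
            else:
                nd += 1.0
            current = mutant
        paths.append((blocked, sd, nd))
    valid = [(sd, nd) for blocked, sd, nd in paths if not blocked]
    if not valid:
        valid = [(sd, nd) for _, sd, nd in paths]
    sd = sum(v[0] for v in valid) / len(valid)
    nd = sum(v[1] for v in valid) / len(valid)
    return sd, nd


@dataclass(frozen=True)
class RateEstimate:
    """NG86 rate estimate for one aligned codon pair of sequences.

    ``dS``/``dN`` are NaN with the corresponding ``*_undefined`` flag set
    when the Jukes-Cantor logarithm argument is non-positive.  ``saturated``
    marks dS > 3, beyond which dS carries no usable signal.
    """

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float
    dS_undefined: bool
    dN_undefined: bool
    saturated: bool


def _jukes_cantor(p: float) -> tuple[float, bool]:
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        return float("nan"), True
    d = -0.75 * float(np.log(arg))
    return (d if d != 0.0 else 0.0), False


def _validate_codons(seq: str, which: str) -> list[str]:
    seq = seq.upper()
    if len(seq) % 3 != 0:
        raise FrameError(f"{which} sequence length {len(seq)} is not a multiple of 3")
    if set(seq) - set("ACGT"):
        raise SequenceFormatError(f"{which} sequence has characters outside ACGT")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    stops = [i for i, c in enumerate(codons) if c in _STOPS]
    if stops:
        raise ParameterError(f"{which} sequence contains stop codon at codon {stops[0]}")
    return codons


def ng86(codons_a: str, codons_b: str) -> RateEstimate:
    """Nei-Gojobori (1986) dN/dS between two aligned coding sequences.

    Sites: the average over the two sequences of per-codon synonymous-site
    fractions; S + N = 3 x codons.  Differences: per codon, the equal-
    weighted average over minimal mutational pathways (stop-crossing
    pathways excluded).  Proportions pS = Sd/S and pN = Nd/N receive the
    Jukes-Cantor correction d = -(3/4) ln(1 - 4p/3).
    """
    ca = _validate_codons(codons_a, "first")
    cb = _validate_codons(codons_b, "second")
    if len(ca) != len(cb):
        raise ParameterError(f"length mismatch: {len(ca)} vs {len(cb)} codons")
    if not ca:
        raise EmptyInputError("ng86 requires at least one codon")
    S = (sum(map(_syn_fraction, ca)) + sum(map(_syn_fraction, cb))) / 2.0
    N = 3.0 * len(ca) - S
    Sd = Nd = 0.0
    for c1, c2 in zip(ca, cb):
        sd, nd = _pair_differences(c1, c2)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS, dS_undef = _jukes_cantor(pS)
    dN, dN_undef = _jukes_cantor(pN)
    return RateEstimate(
        S=S,
        N=N,
        Sd=Sd,
        Nd=Nd,
        pS=pS,
        pN=pN,
        dS=dS,
        dN=dN,
        dS_undefined=dS_undef,
        dN_undefined=dN_undef,
        saturated=(not dS_undef) and dS > SATURATION_DS,
    )


def compare_rates(groups: dict[str, "np.ndarray"]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summaries and pairwise rank-sum tests of dN grouped by bias class.

    Returns (per-group summary with n/median/quartiles, pairwise two-sided
    Mann-Whitney U p-values BH-adjusted across pairs).  Groups with fewer
    than 2 values are dropped with a warning.
    """
    kept = {}
    for name, values in groups.items():
        arr = np.asarray(values, dtype=float)
        arr = arr[np.isfinite(arr)]
        if len(arr) < 2:
            warnings.warn(f"dropping group {name!r} with <2 finite values", stacklevel=2)
            continue
        kept[name] = arr
    if len(kept) < 2:
        raise InsufficientDataError("need >=2 groups with >=2 values each")
    summary = pd.DataFrame(
        {
            name: {
                "n": len(arr),
                "median": float(np.median(arr)),
                "q1": float(np.percentile(arr, 25)),
                "q3": float(np.percentile(arr, 75)),
            }
            for name, arr in kept.items()
        }
    ).T
    summary.index.name = "group"
    pairs = list(itertools.combinations(sorted(kept), 2))
    rows = []
    for g1, g2 in pairs:
        res = stats.mannwhitneyu(kept[g1], kept[g2], alternative="two-sided")
        rows.append({"group1": g1, "group2": g2, "U": float(res.statistic), "p": float(res.pvalue)})
    pairwise = pd.DataFrame(rows)
    pairwise["padj"] = bh_adjust(pairwise["p"].to_numpy())
    return summary, pairwise
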