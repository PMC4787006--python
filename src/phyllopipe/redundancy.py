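"""Contig redundancy reduction and assembly statistics.

De novo transcriptome assemblies carry many near-identical contigs
(alternative transcripts of one gene, typically differing by point variants
and large facultative-exon indels while the aligning blocks are essentially
identical).  This module reduces that redundancy the way the original
analysis did: find pairs of contigs that share a high-identity local match
(>= 99% identity over >= 200 bp, spanning >= 50% of both sequences), link
matching contigs into clusters, and keep the longest member of each cluster.

The pairwise aligner is an exact-seed (k = 31) anchored, *ungapped* local
aligner: for every diagonal carrying a shared 31-mer it finds the
maximum-scoring ungapped segment (match +1, mismatch -2).  Ungapped segments
reproduce megablast HSP semantics for this task — a large alternative-exon
indel terminates an HSP rather than being bridged, which is essential
because identity here counts gap columns as mismatch columns, so a bridged
50-300 bp deletion could never pass the 0.99 identity cutoff.  Any segment
that passes the default filter (>= 200 columns at >= 99% identity) contains
a >= 66 bp exact run by pigeonhole and is therefore guaranteed to be seeded,
so a ``None`` return certifies that no passing match exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from ._util import check_fraction, check_positive
from .errors import EmptyInputError, SequenceFormatError, UnknownIdError

__all__ = [
    "Contig",
    "MatchParams",
    "PairwiseMatch",
    "Cluster",
    "AssemblyStats",
    "align_pair",
    "passes_filter",
    "pairwise_matches",
    "cluster_contigs",
    "select_representatives",
    "reduce_redundancy",
    "assembly_stats",
]

_ALPHABET = frozenset(b"ACGTN")

MATCH_SCORE = 1
MISMATCH_SCORE = -2
SEED_K = 31


@dataclass(frozen=True)
class Contig:
    """An assembled transcript sequence (A, C, G, T, N alphabet)."""

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class MatchParams:
    """Filter thresholds for accepting a pairwise match as redundancy.

    Defaults follow the published clustering rule: identity cutoff 0.99 over
    at least 200 bp, spanning at least 50% of both the query and the hit.
    """

    min_identity: float = 0.99
    min_match_len: int = 200
    min_coverage_both: float = 0.50

    def __post_init__(self) -> None:
        check_fraction(self.min_identity, "min_identity", closed_low=False)
        check_positive(self.min_match_len, "min_match_len", integer=True)
        check_fraction(self.min_coverage_both, "min_coverage_both", closed_low=False)


@dataclass(frozen=True)
class PairwiseMatch:
    """Summary of the best local alignment between two contigs.

    Coordinates are 0-based, half-open, on the forward strand of each
    sequence.  ``identity`` is identical columns / alignment columns;
    ``match_len`` is the number of alignment columns.
    """

    query_id: str
    subject_id: str
    identity: float
    match_len: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    query_cov: float
    subject_cov: float
    score: int = 0


@dataclass
class Cluster:
    member_ids: set = field(default_factory=set)
    representative_id: str = ""


@dataclass(frozen=True)
class AssemblyStats:
    n_contigs: int
    total_bp: int
    shortest: int
    longest: int
    n_gt_500: int
    n_gt_1k: int
    n_gt_10k: int
    mean: int
    median: int
    n50: int


def _encode(contig: Contig) -> np.ndarray:
    raw = contig.seq.upper().encode("ascii", errors="replace")
    arr = np.frombuffer(raw, dtype=np.uint8)
    bad = set(raw) - _ALPHABET
    if bad:
        raise SequenceFormatError(
            f"contig {contig.id!r} contains non-IUPAC characters: "
            f"{sorted(chr(c) for c in bad)}"
        )
    return arr


def _best_segment_on_diagonal(a: np.ndarray, b: np.ndarray, diag: int):
    """Maximum-scoring ungapped segment on one diagonal (Kadane by prefix sums).

    Returns (score, a_start, a_end) or None if the overlap is empty or all
    segments score <= 0.  N positions never count as identities.
    """
    i0 = max(0, -diag)
    i1 = min(len(a), len(b) - diag)
    if i1 - i0 <= 0:
        return None
    a_sub = a[i0:i1]
    b_sub = b[i0 + diag : i1 + diag]
    eq = (a_sub == b_sub) & (a_sub != ord("N"))
    sc = np.where(eq, MATCH_SCORE, MISMATCH_SCORE).astype(np.int64)
    prefix = np.concatenate(([0], np.cumsum(sc)))
    run_min = np.minimum.accumulate(prefix[:-1])
    gains = prefix[1:] - run_min
    end_rel = int(np.argmax(gains))
    score = int(gains[end_rel])
    if score <= 0:
        return None
    # rightmost minimal prefix: shortest (densest) segment with the best score,
    # which also guarantees the segment never starts on a mismatch column
    prefix_slice = prefix[: end_rel + 1]
    start_rel = int(np.flatnonzero(prefix_slice == prefix_slice.min())[-1])
    return score, i0 + start_rel, i0 + end_rel + 1


def align_pair(a: Contig, b: Contig, *, k: int = SEED_K) -> PairwiseMatch | None:
    """Best seeded ungapped local alignment between two contigs.

    Scans every diagonal on which the two sequences share an exact k-mer and
    returns the highest-scoring ungapped segment, or ``None`` when no seeded
    diagonal yields a positive-scoring segment.  Symmetric up to the
    query/subject role swap.  Ties between equal-scoring segments break
    deterministically (smallest diagonal offset, then leftmost start).
    """
    if not a.seq or not b.seq:
        raise EmptyInputError("align_pair requires nonempty sequences")
    arr_a = _encode(a)
    arr_b = _encode(b)
    if len(arr_a) < k or len(arr_b) < k:
        return None

    seq_a = a.seq.upper()
    seq_b = b.seq.upper()
    index: dict[str, list[int]] = {}
    for i in range(len(seq_a) - k + 1):
        kmer = seq_a[i : i + k]
        if "N" not in kmer:
            index.setdefault(kmer, []).append(i)
    diagonals: set[int] = set()
    for j in range(len(seq_b) - k + 1):
        hits = index.get(seq_b[j : j + k])
        if hits:
            for i in hits:
                diagonals.add(j - i)

    best = None  # (-score, |diag|, start, diag, a_start, a_end)
    for diag in sorted(diagonals, key=lambda d: (abs(d), d)):
        seg = _best_segment_on_diagonal(arr_a, arr_b, diag)
        if seg is None:
            continue
        score, a_start, a_end = seg
        key = (-score, abs(diag), a_start)
        if best is None or key < best[0]:
            best = (key, diag, a_start, a_end, score)
    if best is None:
        return None
    _, diag, a_start, a_end, score = best
    cols = a_end - a_start
    matches = int(
        np.count_nonzero(
            (arr_a[a_start:a_end] == arr_b[a_start + diag : a_end + diag])
            & (arr_a[a_start:a_end] != ord("N"))
        )
    )
    return PairwiseMatch(
        query_id=a.id,
        subject_id=b.id,
        identity=matches / cols,
        match_len=cols,
        query_start=a_start,
        query_end=a_end,
        subject_start=a_start + diag,
        subject_end=a_end + diag,
        query_cov=cols / len(arr_a),
        subject_cov=cols / len(arr_b),
        score=score,
    )


def passes_filter(m: PairwiseMatch, p: MatchParams = MatchParams()) -> bool:
    """Published acceptance rule for a redundancy match (all four conditions)."""
    return (
        m.identity >= p.min_identity
        and m.match_len >= p.min_match_len
        and m.query_cov >= p.min_coverage_both
        and m.subject_cov >= p.min_coverage_both
    )


def pairwise_matches(
    contigs: list[Contig],
    params: MatchParams = MatchParams(),
    *,
    k: int = SEED_K,
    index_stride: int = 32,
) -> list[PairwiseMatch]:
    """All-vs-all redundancy matches that pass ``params``.

    Candidate pairs are pre-screened with a strided k-mer index: one contig
    of a candidate pair is indexed every ``index_stride`` positions and the
    other is scanned at every position, so any shared exact run of length
    >= k + index_stride - 1 (= 62 bp at the defaults, shorter than the 66 bp
    run guaranteed inside any passing match) is certain to be detected.
    """
    if k + index_stride - 1 > 66:
        raise ValueError("index_stride too large for guaranteed seeding at k=31")
    ids = [c.id for c in contigs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate contig ids in input")
    index: dict[str, list[int]] = {}
    for ci, contig in enumerate(contigs):
        seq = contig.seq.upper()
        for pos in range(0, max(len(seq) - k + 1, 0), index_stride):
            kmer = seq[pos : pos + k]
            if "N" not in kmer:
                index.setdefault(kmer, []).append(ci)
    candidates: set[tuple[int, int]] = set()
    for ci, contig in enumerate(contigs):
        seq = contig.seq.upper()
        partners: set[int] = set()
        for pos in range(len(seq) - k + 1):
            hits = index.get(seq[pos : pos + k])
            if hits:
                partners.update(hits)
        for cj in partners:
            if cj != ci:
                candidates.add((min(ci, cj), max(ci, cj)))
    out = []
    for ci, cj in sorted(candidates):
        m = align_pair(contigs[ci], contigs[cj], k=k)
        if m is not None and passes_filter(m, params):
            out.append(m)
    return out


def cluster_contigs(contigs: list[Contig], matches: list[PairwiseMatch]) -> list[Cluster]:
    """Single-linkage clusters: connected components of the match graph.

    Every contig lands in exactly one cluster; contigs without any passing
    match become singletons.  Raises :class:`UnknownIdError` if a match
    references an id absent from ``contigs``.
    """
    idx = {c.id: i for i, c in enumerate(contigs)}
    n = len(contigs)
    rows, cols = [], []
    for m in matches:
        for cid in (m.query_id, m.subject_id):
            if cid not in idx:
                raise UnknownIdError(f"match references unknown contig id {cid!r}")
        rows.append(idx[m.query_id])
        cols.append(idx[m.subject_id])
    graph = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)
    clusters = [Cluster() for _ in range(n_comp)]
    for contig, label in zip(contigs, labels):
        clusters[label].member_ids.add(contig.id)
    by_id = {c.id: c for c in contigs}
    for cl in clusters:
        # longest member; ties break to the lexicographically smallest id
        cl.representative_id = min(cl.member_ids, key=lambda i: (-by_id[i].length, i))
    clusters.sort(key=lambda cl: cl.representative_id)
    return clusters


def select_representatives(clusters: list[Cluster], contigs: list[Contig]) -> list[Contig]:
    """One contig per cluster: the longest member (smallest id on ties)."""
    by_id = {c.id: c for c in contigs}
    out = []
    for cl in clusters:
        missing = cl.member_ids - by_id.keys()
        if missing:
            raise UnknownIdError(f"cluster members not in contig set: {sorted(missing)}")
        rep = min(cl.member_ids, key=lambda i: (-by_id[i].length, i))
        out.append(by_id[rep])
    out.sort(key=lambda c: c.id)
    return out


def reduce_redundancy(
    contigs: list[Contig],
    params: MatchParams = MatchParams(),
    *,
    matches: list[PairwiseMatch] | None = None,
) -> tuple[list[Contig], list[Cluster]]:
    """Full reduction: match (unless precomputed), cluster, keep longest."""
    if matches is None:
        matches = pairwise_matches(contigs, params)
    else:
        matches = [m for m in matches if passes_filter(m, params)]
    clusters = cluster_contigs(contigs, matches)
    return select_representatives(clusters, contigs), clusters


def assembly_stats(contigs: list[Contig]) -> AssemblyStats:
    """Assembly summary statistics over contig lengths.

    N50 is the observed length L, scanning from the longest contig down,
    at which the cumulative length first reaches half the total.  The mean
    is rounded to the nearest integer bp and the median is the lower-middle
    element for even n, matching the integer convention of published
    assembly tables.  Size-class counts use strict inequalities.
    """
    if not contigs:
        raise EmptyInputError("assembly_stats requires at least one contig")
    lengths = np.sort(np.array([c.length for c in contigs], dtype=np.int64))[::-1]
    total = int(lengths.sum())
    cumulative = np.cumsum(lengths)
    n50 = int(lengths[int(np.searchsorted(cumulative, total / 2))])
    n = len(lengths)
    return AssemblyStats(
        n_contigs=n,
        total_bp=total,
        shortest=int(lengths[-1]),
        longest=int(lengths[0]),
        n_gt_500=int(np.count_nonzero(lengths > 500)),
        n_gt_1k=int(np.count_nonzero(lengths > 1000)),
        n_gt_10k=int(np.count_nonzero(lengths > 10000)),
        mean=int(np.floor(total / n + 0.5)),
        median=int(np.sort(lengths)[(n - 1) // 2]),
        n50=n50,
    )
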