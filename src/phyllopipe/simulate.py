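"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the study conditions of a two-morph insect
transcriptome experiment: a redundant contig set with near-identical
alternative-transcript variants, negative-binomial count matrices for two
conditions (leaf-galling GA and root-feeding RA) with two replicates each
plus one egg library, a six-member gene family carrying ~10% of mapped
reads in GA and RA but ~0.04% in eggs, AT-rich coding sequences (GC3 near
24.8%), GO annotations with planted enrichment among DE contigs, codon
pairs evolved at controlled synonymous/non-synonymous intensities, and Cq
tables drawn from known quantities and per-gene standard curves.

All randomness flows from a single integer seed through named substreams
(one per generator), so adding a generator never perturbs the draws of the
others and a fixed seed reproduces byte-identical outputs.

Design constraints that make the planted truth exactly recoverable
downstream (documented in the methods note): variant point mutations sit
on an evenly spaced jittered grid so no aligned block dips below the
identity cutoff; alternative-exon deletions start within the first fifth
of the transcript so the downstream colinear block always spans at least
half of both sequences; codon pairs accept at most one substitution per
codon so realized difference counts coincide with NG86 pathway counts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._util import check_fraction, check_positive, substream
from .errors import ParameterError
from .expression import CountMatrix
from .comparative import GENETIC_CODE
from .redundancy import Contig

__all__ = [
    "SimSpec",
    "TruthTable",
    "gen_transcriptome",
    "gen_counts",
    "gen_annotations",
    "gen_codon_pairs",
    "gen_qpcr",
    "gen_family_membership",
]

_SENSE_CODONS = tuple(sorted(c for c, aa in GENETIC_CODE.items() if aa != "*"))
_STOP_SET = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")

# per-member share profile of the high-expression family, mirroring the
# observed strongly skewed within-family composition
_FAMILY_PROFILE = np.array([3.80, 1.94, 1.10, 0.68, 0.33, 0.002])

DEFAULT_FAMILY_PLAN = {
    "many_to_many": 8,
    "many_A_to_one_B": 6,
    "many_B_to_one_A": 4,
    "one_to_one": 40,
    "A_specific_family": 5,
    "B_specific_family": 3,
    "A_singleton": 20,
    "B_singleton": 12,
}


@dataclass(frozen=True)
class SimSpec:
    """Parameters of the synthetic experiment (defaults = study conditions)."""

    seed: int = 0
    # transcriptome
    n_base_transcripts: int = 300
    redundancy_rate: float = 0.3
    variant_identity: float = 0.995
    deletion_prob: float = 0.5
    length_range: tuple = (1200, 3000)
    gc1_target: float = 0.45
    gc2_target: float = 0.38
    gc3_target: float = 0.248
    # counts
    n_replicates: int = 2
    depth: int = 500_000
    de_fraction: float = 0.15
    de_log2fc: float = 2.0
    dispersion: float = 0.05
    highshare_family_size: int = 6
    highshare_total_fraction: float = 0.10
    egg_family_fraction: float = 0.0004
    # annotations
    n_go_terms: int = 50
    go_baseline_prob: float = 0.05
    enriched_terms: tuple = (("GO:0000001", 10.0),)
    # codon pairs: (n_pairs, codons per pair, per-site substitution
    # probability, non-synonymous acceptance intensity in [0, 1])
    codonpair_params: tuple = (200, 100, 0.03, 0.2)
    # qPCR
    qpcr_noise_sd: float = 0.15
    qpcr_bio_sd: float = 0.10
    qpcr_targets: tuple = (
        ("apyrase-1", 2.5),
        ("take-out", 1.5),
        ("apyrase-2", -2.0),
        ("trypsin-like", -3.0),
    )
    qpcr_reference_genes: tuple = ("transaldolase-like", "ATP-synthase-like")
    qpcr_n_bio: int = 3
    qpcr_n_tech: int = 3
    # family membership plan: category -> number of families (or singletons)
    family_plan: tuple = tuple(sorted(DEFAULT_FAMILY_PLAN.items()))

    def __post_init__(self) -> None:
        check_positive(self.n_base_transcripts, "n_base_transcripts", integer=True)
        check_fraction(self.redundancy_rate, "redundancy_rate")
        check_fraction(self.variant_identity, "variant_identity")
        check_fraction(self.deletion_prob, "deletion_prob")
        check_fraction(self.de_fraction, "de_fraction")
        check_fraction(self.gc1_target, "gc1_target")
        check_fraction(self.gc2_target, "gc2_target")
        check_fraction(self.gc3_target, "gc3_target")
        check_fraction(self.highshare_total_fraction, "highshare_total_fraction")
        check_fraction(self.egg_family_fraction, "egg_family_fraction")
        check_fraction(self.go_baseline_prob, "go_baseline_prob", closed_low=False)
        check_positive(self.n_replicates, "n_replicates", integer=True)
        check_positive(self.depth, "depth", integer=True)
        check_positive(self.n_go_terms, "n_go_terms", integer=True)
        if self.dispersion < 0:
            raise ParameterError(f"dispersion must be >= 0, got {self.dispersion}")
        if self.highshare_family_size < 0:
            raise ParameterError("highshare_family_size must be >= 0")
        if self.length_range[0] < 600 or self.length_range[1] < self.length_range[0]:
            raise ParameterError(f"invalid length_range {self.length_range}")
        if self.de_log2fc < 0:
            raise ParameterError("de_log2fc must be >= 0")
        for term, odds in self.enriched_terms:
            if odds <= 0:
                raise ParameterError(f"enriched term {term}: odds ratio must be > 0")
        n_pairs, n_codons, sub_prob, omega = self.codonpair_params
        check_positive(n_pairs, "codonpair_params.n_pairs", integer=True)
        check_positive(n_codons, "codonpair_params.codons_per_pair", integer=True)
        check_fraction(sub_prob, "codonpair_params.sub_prob")
        check_fraction(omega, "codonpair_params.nonsyn_intensity")
        if self.qpcr_noise_sd < 0 or self.qpcr_bio_sd < 0:
            raise ParameterError("qPCR noise standard deviations must be >= 0")

    def with_(self, **kwargs) -> "SimSpec":
        return replace(self, **kwargs)


@dataclass
class TruthTable:
    """Planted ground truth, one part per generator, assembled per run."""

    clusters: pd.DataFrame | None = None
    expression: pd.DataFrame | None = None
    annotations: pd.DataFrame | None = None
    codon_pairs: pd.DataFrame | None = None
    qpcr: dict | None = None
    families: pd.DataFrame | None = None


def _sample_codons(rng: np.random.Generator, n: int, gc: tuple[float, float, float]) -> np.ndarray:
    """(n, 3) array of nucleotide bytes with per-position GC targets, no stops."""
    letters = np.frombuffer(b"ACGT", dtype=np.uint8)
    probs = [
        np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2]) for g in gc
    ]  # order A, C, G, T
    out = np.empty((n, 3), dtype=np.uint8)
    for pos in range(3):
        out[:, pos] = rng.choice(letters, size=n, p=probs[pos])
    stops = {tuple(s.encode()) for s in _STOP_SET}
    while True:
        is_stop = np.array([tuple(row) in stops for row in out])
        if not is_stop.any():
            break
        k = int(is_stop.sum())
        for pos in range(3):
            out[is_stop, pos] = rng.choice(letters, size=k, p=probs[pos])
    return out


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Plant point mutations on an evenly spaced jittered grid.

    Spacing 1/rate with jitter in [0.25, 0.75] of a step keeps every
    window's mutation load within a factor ~1.5 of the target rate, so
    local identity can never dip below the clustering cutoff.
    """
    arr = bytearray(seq.encode("ascii"))
    L = len(arr)
    m = max(1, round(rate * L))
    spacing = L / m
    letters = b"ACGT"
    for j in range(m):
        pos = int((j + rng.uniform(0.25, 0.75)) * spacing)
        pos = min(pos, L - 1)
        current = arr[pos]
        choices = [c for c in letters if c != current]
        arr[pos] = choices[rng.integers(0, len(choices))]
    return arr.decode("ascii")


def gen_transcriptome(spec: SimSpec) -> tuple[list[Contig], pd.DataFrame]:
    """Contig set with planted redundancy and its true cluster partition.

    Base transcripts are coding-frame sequences (ATG + sense codons + stop,
    flanked by short UTRs) with per-position GC matching the spec targets.
    A ``redundancy_rate`` fraction of bases receives 1-3 near-identical
    variants: point mutations at rate 1 - variant_identity and, with
    probability ``deletion_prob``, one internal deletion of 50-300 bp
    mimicking a facultative exon.  Truth records the intended partition;
    the base is always the longest member of its cluster.
    """
    rng = substream(spec.seed, "transcriptome")
    gc = (spec.gc1_target, spec.gc2_target, spec.gc3_target)
    lo, hi = spec.length_range
    contigs: list[Contig] = []
    truth_rows = []
    for i in range(spec.n_base_transcripts):
        n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
        body = _sample_codons(rng, n_codons, gc).reshape(-1).tobytes().decode("ascii")
        utr5 = "".join(rng.choice(list("ACGT"), size=int(rng.integers(20, 80))))
        utr3 = "".join(rng.choice(list("ACGT"), size=int(rng.integers(20, 80))))
        seq = utr5 + "ATG" + body + "TAA" + utr3
        base_id = f"comp{i:05d}_c0_seq1"
        contigs.append(Contig(base_id, seq))
        truth_rows.append(
            {"contig_id": base_id, "cluster_id": base_id, "is_variant": False, "has_deletion": False}
        )
        if rng.random() < spec.redundancy_rate:
            n_var = int(rng.integers(1, 4))
            for v in range(n_var):
                var = _mutate(rng, seq, 1.0 - spec.variant_identity)
                has_del = bool(rng.random() < spec.deletion_prob)
                if has_del:
                    L = len(var)
                    d = int(rng.integers(50, 301))
                    start = int(rng.integers(int(0.05 * L), int(0.20 * L)))
                    var = var[:start] + var[start + d :]
                var_id = f"comp{i:05d}_c0_seq{v + 2}"
                contigs.append(Contig(var_id, var))
                truth_rows.append(
                    {
                        "contig_id": var_id,
                        "cluster_id": base_id,
                        "is_variant": True,
                        "has_deletion": has_del,
                    }
                )
    return contigs, pd.DataFrame(truth_rows)


def gen_counts(spec: SimSpec, contigs: list[Contig]) -> tuple[CountMatrix, pd.DataFrame]:
    """NB count matrix over GA/RA replicates plus one egg library.

    Expected library totals equal ``depth``.  DE contigs split their fold
    change symmetrically (x 2^(+/- lfc/2)) between the two conditions so
    library compositions stay balanced and size factors remain near 1.
    The high-share family receives ``highshare_total_fraction`` of the
    expected reads in GA and in RA but only ``egg_family_fraction`` in the
    egg library, echoing the observed oviparity-associated expression.
    """
    if not contigs:
        raise ParameterError("contig set must be nonempty")
    rng = substream(spec.seed, "counts")
    ids = [c.id for c in contigs]
    n = len(ids)
    fam_size = min(spec.highshare_family_size, n)
    fam_idx = rng.choice(n, size=fam_size, replace=False) if fam_size else np.array([], int)
    is_fam = np.zeros(n, dtype=bool)
    is_fam[fam_idx] = True

    weights = rng.lognormal(mean=0.0, sigma=1.5, size=n)
    weights[is_fam] = 0.0
    weights /= weights.sum()
    fam_frac = spec.highshare_total_fraction if fam_size else 0.0
    base_mu = weights * (1.0 - fam_frac) * spec.depth

    non_fam = np.flatnonzero(~is_fam)
    n_de = int(round(spec.de_fraction * len(non_fam)))
    de_idx = rng.choice(non_fam, size=n_de, replace=False) if n_de else np.array([], int)
    delta = np.zeros(n)
    if n_de:
        signs = rng.choice([-1.0, 1.0], size=n_de)
        delta[de_idx] = signs * spec.de_log2fc

    mu_ga = base_mu * 2.0 ** (-delta / 2.0)
    mu_ra = base_mu * 2.0 ** (+delta / 2.0)
    mu_egg = weights * (1.0 - spec.egg_family_fraction) * spec.depth
    if fam_size:
        profile = _FAMILY_PROFILE[:fam_size]
        profile = profile / profile.sum()
        mu_ga[fam_idx] = profile * fam_frac * spec.depth
        mu_ra[fam_idx] = profile * fam_frac * spec.depth
        mu_egg[fam_idx] = profile * spec.egg_family_fraction * spec.depth

    def draw(mu: np.ndarray) -> np.ndarray:
        if spec.dispersion == 0:
            return rng.poisson(mu)
        r = 1.0 / spec.dispersion
        return rng.negative_binomial(r, r / (r + np.maximum(mu, 1e-300)))

    libraries, conditions, replicates, columns = [], [], [], {}
    for rep in range(1, spec.n_replicates + 1):
        name = f"GA_{rep}"
        libraries.append(name), conditions.append("GA"), replicates.append(rep)
        columns[name] = draw(mu_ga)
    for rep in range(1, spec.n_replicates + 1):
        name = f"RA_{rep}"
        libraries.append(name), conditions.append("RA"), replicates.append(rep)
        columns[name] = draw(mu_ra)
    libraries.append("EGG_1"), conditions.append("EGG"), replicates.append(1)
    columns["EGG_1"] = draw(mu_egg)

    counts = pd.DataFrame(columns, index=pd.Index(ids, name="contig_id"))
    design = pd.DataFrame(
        {"condition": conditions, "replicate": replicates}, index=pd.Index(libraries, name="library")
    )
    truth = pd.DataFrame(
        {
            "contig_id": ids,
            "is_de": delta != 0,
            "true_log2fc": delta,
            "is_family": is_fam,
            "mu_ga": mu_ga,
            "mu_ra": mu_ra,
            "mu_egg": mu_egg,
        }
    )
    return CountMatrix(counts, design), truth


def gen_annotations(
    spec: SimSpec, contigs: list[Contig], de_truth: pd.DataFrame
) -> tuple[dict[str, set], pd.DataFrame]:
    """Contig -> GO term sets with planted enrichment among true-DE contigs.

    Background terms are assigned uniformly at the baseline probability.
    Each enriched term is assigned to DE contigs at the probability giving
    exactly the specified odds ratio against the baseline.
    """
    rng = substream(spec.seed, "annotations")
    ids = [c.id for c in contigs]
    de_ids = set(de_truth.loc[de_truth["is_de"], "contig_id"])
    if spec.enriched_terms and not de_ids:
        raise ParameterError("enriched_terms requested but the DE truth list is empty")
    p0 = spec.go_baseline_prob
    ann: dict[str, set] = {cid: set() for cid in ids}
    rows = []
    background = [f"GO:{1000001 + t:07d}" for t in range(spec.n_go_terms)]
    for term in background:
        hit = rng.random(len(ids)) < p0
        for cid, h in zip(ids, hit):
            if h:
                ann[cid].add(term)
        rows.append({"term": term, "odds_ratio": 1.0, "enriched": False})
    for term, odds in spec.enriched_terms:
        odds0 = p0 / (1.0 - p0)
        p1 = odds * odds0 / (1.0 + odds * odds0)
        probs = np.where([cid in de_ids for cid in ids], p1, p0)
        hit = rng.random(len(ids)) < probs
        for cid, h in zip(ids, hit):
            if h:
                ann[cid].add(term)
        rows.append({"term": term, "odds_ratio": float(odds), "enriched": odds != 1.0})
    ann = {cid: terms for cid, terms in ann.items() if terms}
    return ann, pd.DataFrame(rows)


def gen_codon_pairs(
    spec: SimSpec, *, stream: str = "codonpairs"
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Aligned codon-sequence pairs evolved at known syn/nonsyn intensity.

    Sequence b evolves from a by per-site substitution at the given
    probability; proposals creating stop codons are rejected, synonymous
    proposals are always accepted and non-synonymous ones accepted with
    probability ``nonsyn_intensity``.  At most one substitution is accepted
    per codon, so the realized difference counts recorded in the truth
    table are exactly the NG86 pathway counts.
    """
    n_pairs, n_codons, sub_prob, omega = spec.codonpair_params
    rng = substream(spec.seed, stream)
    pairs: list[tuple[str, str]] = []
    rows = []
    for pair_idx in range(n_pairs):
        ancestor = [
            _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), size=n_codons)
        ]
        derived = []
        syn = nonsyn = 0
        for codon in ancestor:
            new = codon
            for site in range(3):
                if rng.random() >= sub_prob:
                    continue
                alt = "ACGT".replace(codon[site], "")[rng.integers(0, 3)]
                mutant = codon[:site] + alt + codon[site + 1 :]
                if mutant in _STOP_SET:
                    continue
                synonymous = GENETIC_CODE[mutant] == GENETIC_CODE[codon]
                if not synonymous and rng.random() >= omega:
                    continue
                new = mutant
                if synonymous:
                    syn += 1
                else:
                    nonsyn += 1
                break  # at most one accepted substitution per codon
            derived.append(new)
        pairs.append(("".join(ancestor), "".join(derived)))
        rows.append({"pair_id": pair_idx, "syn_diffs": syn, "nonsyn_diffs": nonsyn})
    return pairs, pd.DataFrame(rows)


def gen_qpcr(spec: SimSpec) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Cq tables from known quantities plus per-gene dilution standards.

    Each gene gets a standard curve with slope near -1/log10(2) (perfect
    doubling) and Cq = intercept + slope x log10(quantity) + N(0, noise).
    Target genes carry the planted condition fold changes split
    symmetrically between GA and RA; the two reference genes are invariant.
    Emits ``qpcr_n_bio`` biological x ``qpcr_n_tech`` technical replicates
    per condition and gene, and a serial ten-fold dilution series (in
    duplicate) per gene.  Truth holds curves, per-replicate quantities and
    the planted log2 fold changes.
    """
    rng = substream(spec.seed, "qpcr")
    genes = list(spec.qpcr_targets) + [(g, 0.0) for g in spec.qpcr_reference_genes]
    perfect_slope = -1.0 / np.log10(2.0)
    curve_rows, cq_rows, std_rows, qty_rows = [], [], [], []
    for gene, lfc in genes:
        slope = perfect_slope * (1.0 + rng.normal(0.0, 0.02))
        intercept = float(rng.uniform(28.0, 34.0))
        curve_rows.append(
            {"gene": gene, "slope": slope, "intercept": intercept, "true_log2fc": lfc}
        )
        for lq in np.arange(0.0, -5.0, -1.0):
            for rep in (1, 2):
                std_rows.append(
                    {
                        "gene": gene,
                        "log10_quantity": float(lq),
                        "replicate": rep,
                        "cq": intercept + slope * lq + rng.normal(0.0, spec.qpcr_noise_sd),
                    }
                )
        base_q = 10.0 ** rng.uniform(-1.5, -0.5)
        for condition, half in (("GA", -0.5), ("RA", +0.5)):
            q_cond = base_q * 2.0 ** (half * lfc)
            for bio in range(1, spec.qpcr_n_bio + 1):
                q_bio = q_cond * 2.0 ** rng.normal(0.0, spec.qpcr_bio_sd)
                qty_rows.append(
                    {"gene": gene, "condition": condition, "bio_rep": bio, "quantity": q_bio}
                )
                for tech in range(1, spec.qpcr_n_tech + 1):
                    cq_rows.append(
                        {
                            "gene": gene,
                            "condition": condition,
                            "bio_rep": bio,
                            "tech_rep": tech,
                            "cq": intercept
                            + slope * np.log10(q_bio)
                            + rng.normal(0.0, spec.qpcr_noise_sd),
                        }
                    )
    truth = {
        "curves": pd.DataFrame(curve_rows),
        "quantities": pd.DataFrame(qty_rows),
        "log2fc": pd.Series({g: fc for g, fc in genes}, name="true_log2fc"),
    }
    return pd.DataFrame(cq_rows), pd.DataFrame(std_rows), truth


def gen_family_membership(spec: SimSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-species gene -> family membership with a known category plan.

    For each homology category the plan requests a number of families (or
    singleton genes); "many" sides draw 2-4 members.  Truth is the plan
    itself, so the category bookkeeping can be checked for exact recovery.
    """
    rng = substream(spec.seed, "families")
    plan = dict(spec.family_plan)
    unknown = set(plan) - {
        "many_to_many",
        "many_A_to_one_B",
        "many_B_to_one_A",
        "one_to_one",
        "A_specific_family",
        "B_specific_family",
        "A_singleton",
        "B_singleton",
    }
    if unknown:
        raise ParameterError(f"unknown family categories in plan: {sorted(unknown)}")
    rows = []
    fam_counter = gene_counter = 0

    def many() -> int:
        return int(rng.integers(2, 5))

    def add_family(nA: int, nB: int) -> None:
        nonlocal fam_counter, gene_counter
        fam_id = f"FAM{fam_counter:05d}"
        fam_counter += 1
        for species, count in (("A", nA), ("B", nB)):
            for _ in range(count):
                rows.append(
                    {"gene_id": f"g{gene_counter:06d}", "family_id": fam_id, "species": species}
                )
                gene_counter += 1

    def add_singleton(species: str) -> None:
        nonlocal gene_counter
        rows.append(
            {"gene_id": f"g{gene_counter:06d}", "family_id": "-", "species": species}
        )
        gene_counter += 1

    for _ in range(plan.get("many_to_many", 0)):
        add_family(many(), many())
    for _ in range(plan.get("many_A_to_one_B", 0)):
        add_family(many(), 1)
    for _ in range(plan.get("many_B_to_one_A", 0)):
        add_family(1, many())
    for _ in range(plan.get("one_to_one", 0)):
        add_family(1, 1)
    for _ in range(plan.get("A_specific_family", 0)):
        add_family(many(), 0)
    for _ in range(plan.get("B_specific_family", 0)):
        add_family(0, many())
    for _ in range(plan.get("A_singleton", 0)):
        add_singleton("A")
    for _ in range(plan.get("B_singleton", 0)):
        add_singleton("B")
    truth = pd.DataFrame(
        [{"category": cat, "n_families": n} for cat, n in sorted(plan.items())]
    )
    return pd.DataFrame(rows), truth
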