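"""Redundancy clustering, the seeded ungapped aligner and assembly stats."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phyllopipe.errors import EmptyInputError, SequenceFormatError, UnknownIdError
from phyllopipe.redundancy import (
    AssemblyStats,
    Contig,
    MatchParams,
    PairwiseMatch,
    align_pair,
    assembly_stats,
    cluster_contigs,
    pairwise_matches,
    passes_filter,
    reduce_redundancy,
    select_representatives,
)

from conftest import random_contig
from oracles import n50_bruteforce, ungapped_local_score


def match(identity, length, qcov, scov):
    return PairwiseMatch(
        query_id="q", subject_id="s", identity=identity, match_len=length,
        query_start=0, query_end=length, subject_start=0, subject_end=length,
        query_cov=qcov, subject_cov=scov,
    )


class TestAlignPair:
    def test_identical_sequences_full_match(self, rng):
        c = random_contig(rng, "a", 300)
        m = align_pair(c, Contig("b", c.seq))
        assert m.identity == 1.0
        assert m.match_len == 300
        assert m.query_cov == 1.0 and m.subject_cov == 1.0

    def test_shared_exact_block_found(self, rng):
        block = "".join(rng.choice(list("ACGT"), size=250))
        a = Contig("a", "".join(rng.choice(list("ACGT"), size=75)) + block
                   + "".join(rng.choice(list("ACGT"), size=75)))
        b = Contig("b", "".join(rng.choice(list("ACGT"), size=150)) + block)
        m = align_pair(a, b)
        assert m is not None
        assert m.identity == 1.0
        assert m.match_len >= 250
        assert m.query_cov >= 0.625 and m.subject_cov >= 0.625
        assert passes_filter(m, MatchParams())

    def test_unrelated_sequences_fail_filter(self, rng):
        a = random_contig(rng, "a", 1000)
        b = random_contig(rng, "b", 1000)
        m = align_pair(a, b)
        # seeding requires a shared exact 31-mer, absent between random 1 kb
        # sequences; a passing match would score >= 194, far above the
        # best random ungapped segment
        assert m is None
        assert ungapped_local_score(a.seq, b.seq) < 194

    def test_symmetry_under_role_swap(self, rng):
        a = random_contig(rng, "a", 400)
        b = Contig("b", a.seq[:350] + "ACGT" * 10)
        m1, m2 = align_pair(a, b), align_pair(b, a)
        assert m1.identity == m2.identity
        assert m1.match_len == m2.match_len
        assert (m1.query_start, m1.query_end) == (m2.subject_start, m2.subject_end)

    def test_agrees_with_full_dp_oracle(self, rng):
        # mixed fixture: identical, block-sharing, point-variant, random pairs
        seqs = []
        base = random_contig(rng, "s0", 450)
        seqs.append(base)
        seqs.append(Contig("s1", base.seq))
        var = list(base.seq)
        for pos in (100, 300):
            var[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[var[pos]]
        seqs.append(Contig("s2", "".join(var)))
        seqs.append(Contig("s3", base.seq[:220]))
        for i in range(4, 8):
            seqs.append(random_contig(rng, f"s{i}", int(rng.integers(150, 500))))
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                m = align_pair(seqs[i], seqs[j])
                oracle = ungapped_local_score(seqs[i].seq, seqs[j].seq)
                if m is not None:
                    assert m.score == oracle
                else:
                    assert oracle < 194  # no passing match can exist unseeded

    def test_n_never_counts_as_identity(self):
        a = Contig("a", "ACGT" * 20 + "N" * 40)
        m = align_pair(a, Contig("b", a.seq), k=20)
        assert m.identity < 1.0 or m.match_len == 80

    def test_non_iupac_rejected(self):
        with pytest.raises(SequenceFormatError):
            align_pair(Contig("a", "ACGTX" * 50), Contig("b", "ACGT" * 50))

    def test_empty_sequence_rejected(self):
        with pytest.raises(EmptyInputError):
            align_pair(Contig("a", ""), Contig("b", "ACGT"))


class TestPassesFilter:
    @pytest.mark.parametrize(
        "identity,length,qcov,scov,expected",
        [
            (1.0, 250, 0.625, 0.625, True),
            (1.0, 150, 1.0, 1.0, False),       # below 200 bp
            (0.989, 500, 0.9, 0.9, False),     # below 0.99 identity
            (0.99, 200, 0.5, 0.5, True),       # thresholds are inclusive
            (1.0, 300, 0.49, 0.9, False),      # query coverage fails
            (1.0, 300, 0.9, 0.49, False),      # subject coverage fails
        ],
    )
    def test_rule_application(self, identity, length, qcov, scov, expected):
        assert passes_filter(match(identity, length, qcov, scov)) is expected


class TestClustering:
    def contigs(self, n=4, length=300):
        rng = np.random.default_rng(1)
        return [random_contig(rng, c, length) for c in "ABCD"[:n]]

    def test_no_matches_all_singletons(self):
        cs = self.contigs()
        clusters = cluster_contigs(cs, [])
        assert sorted(len(c.member_ids) for c in clusters) == [1, 1, 1, 1]

    def test_transitive_linkage(self):
        cs = self.contigs()
        ms = [
            PairwiseMatch("A", "B", 1.0, 300, 0, 300, 0, 300, 1.0, 1.0),
            PairwiseMatch("B", "C", 1.0, 300, 0, 300, 0, 300, 1.0, 1.0),
        ]
        clusters = cluster_contigs(cs, ms)
        sizes = sorted(len(c.member_ids) for c in clusters)
        assert sizes == [1, 3]
        big = next(c for c in clusters if len(c.member_ids) == 3)
        assert big.member_ids == {"A", "B", "C"}

    def test_unknown_id_raises(self):
        with pytest.raises(UnknownIdError):
            cluster_contigs(self.contigs(), [PairwiseMatch("A", "Z", 1, 300, 0, 300, 0, 300, 1, 1)])

    def test_partition_conserves_contigs(self):
        cs = self.contigs()
        clusters = cluster_contigs(cs, [PairwiseMatch("A", "D", 1, 300, 0, 300, 0, 300, 1, 1)])
        all_members = [m for c in clusters for m in c.member_ids]
        assert sorted(all_members) == sorted(c.id for c in cs)

    def test_representative_longest_then_lexicographic(self):
        cs = [Contig("A", "A" * 500), Contig("B", "A" * 400),
              Contig("X", "C" * 300), Contig("Y", "C" * 300)]
        ms = [PairwiseMatch("A", "B", 1, 400, 0, 400, 0, 400, 0.8, 1.0),
              PairwiseMatch("X", "Y", 1, 300, 0, 300, 0, 300, 1.0, 1.0)]
        reps = {c.id for c in select_representatives(cluster_contigs(cs, ms), cs)}
        assert reps == {"A", "X"}

    def test_all_singletons_identity(self):
        cs = self.contigs()
        out = select_representatives(cluster_contigs(cs, []), cs)
        assert sorted(c.id for c in out) == sorted(c.id for c in cs)

    def test_planted_redundancy_recovered_and_idempotent(self):
        from sklearn.metrics import adjusted_rand_score

        from phyllopipe.simulate import SimSpec, gen_transcriptome

        contigs, truth = gen_transcriptome(SimSpec(seed=3, n_base_transcripts=60))
        reduced, clusters = reduce_redundancy(contigs)
        assigned = {m: c.representative_id for c in clusters for m in c.member_ids}
        ids = list(truth["contig_id"])
        truth_labels = list(truth["cluster_id"])
        pred_labels = [assigned[i] for i in ids]
        assert adjusted_rand_score(truth_labels, pred_labels) == 1.0
        assert {c.id for c in reduced} == set(truth_labels)
        # idempotence: clustering the representatives yields only singletons
        reduced2, clusters2 = reduce_redundancy(reduced)
        assert all(len(c.member_ids) == 1 for c in clusters2)
        assert len(reduced2) == len(reduced)

    def test_precomputed_match_table_used(self, rng, tmp_path):
        from phyllopipe.io import read_blast_tabular, write_blast_tabular

        base = random_contig(rng, "A", 600)
        cs = [base, Contig("B", base.seq[:500]), random_contig(rng, "C", 400)]
        matches = pairwise_matches(cs)
        path = tmp_path / "matches.tsv"
        write_blast_tabular(matches, path)
        loaded = read_blast_tabular(path, {c.id: c.length for c in cs})
        reduced, _ = reduce_redundancy(cs, matches=loaded)
        assert {c.id for c in reduced} == {"A", "C"}


class TestAssemblyStats:
    def contigs_of(self, lengths):
        return [Contig(f"c{i}", "A" * n) for i, n in enumerate(lengths)]

    def test_single_contig(self):
        s = assembly_stats(self.contigs_of([201]))
        assert s == AssemblyStats(1, 201, 201, 201, 0, 0, 0, 201, 201, 201)

    def test_n50_worked_example(self):
        s = assembly_stats(self.contigs_of([6, 5, 4, 3, 2]))
        assert s.total_bp == 20
        assert s.n50 == 5  # cumulative 6, 11 >= 10

    def test_strict_size_classes(self):
        s = assembly_stats(self.contigs_of([1000, 600, 400]))
        assert s.n_gt_500 == 2
        assert s.n_gt_1k == 0

    def test_median_lower_middle_for_even_n(self):
        assert assembly_stats(self.contigs_of([10, 20, 30, 40])).median == 20

    def test_empty_input_raises(self):
        with pytest.raises(EmptyInputError):
            assembly_stats([])

    @given(st.lists(st.integers(min_value=1, max_value=5000), min_size=1, max_size=50))
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_n50_matches_bruteforce(self, lengths):
        s = assembly_stats(self.contigs_of(lengths))
        assert s.n50 == n50_bruteforce(lengths)
        assert s.shortest <= s.median <= s.longest
        assert s.n50 in lengths
        assert s.n_gt_500 >= s.n_gt_1k >= s.n_gt_10k
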