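"""Share accounting, size factors, BH, the NB Wald test and bias classes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phyllopipe.errors import (
    DegenerateLibraryError,
    DesignError,
    NormalizationError,
    ParameterError,
    UnknownIdError,
)
from phyllopipe.expression import (
    CountMatrix,
    ShareTable,
    bh_adjust,
    classify_bias,
    compute_shares,
    family_share,
    nb_de_test,
    size_factors,
)

from oracles import bh_bruteforce


def make_cm(counts: dict, conditions: dict | None = None) -> CountMatrix:
    df = pd.DataFrame(counts)
    df.index = [f"c{i}" for i in range(len(df))]
    design = None
    if conditions:
        design = pd.DataFrame(
            {"condition": [conditions[lib] for lib in df.columns],
             "replicate": list(range(1, len(df.columns) + 1))},
            index=df.columns,
        )
    return CountMatrix(df, design)


class TestShares:
    def test_single_contig_share_100(self):
        cm = make_cm({"L1": [7], "L2": [123]})
        st_ = compute_shares(cm)
        assert np.allclose(st_.per_library, 100.0)

    def test_simple_arithmetic(self):
        cm = make_cm({"L1": [10, 30, 60]})
        assert list(compute_shares(cm).per_library["L1"]) == [10, 30, 60]

    def test_columns_sum_to_100(self, rng):
        cm = make_cm({f"L{j}": rng.integers(0, 100, size=20) + 1 for j in range(4)})
        sums = compute_shares(cm).per_library.sum(axis=0)
        assert np.allclose(sums, 100.0, atol=1e-9)

    def test_condition_share_is_replicate_mean(self):
        cm = make_cm({"GA_1": [10, 90], "GA_2": [30, 70]},
                     {"GA_1": "GA", "GA_2": "GA"})
        st_ = compute_shares(cm)
        assert np.allclose(st_.per_condition["GA"], [20.0, 80.0])

    def test_zero_total_library_rejected(self):
        with pytest.raises(DegenerateLibraryError):
            make_cm({"L1": [1, 2], "L2": [0, 0]})

    def test_family_share_printed_paralog_table(self):
        # per-copy shares of the oviparity-associated family as published;
        # summing the pea-aphid paralogs for oviparae reproduces the printed
        # family total of 10.59
        pea = pd.DataFrame(
            {"oviparae": [1.84, 4.31, 4.44],
             "viviparae": [0.001, 0.02, 0.003],
             "males": [0.0, 0.02, 0.0]},
            index=["ACYPI49687", "ACYPI49688", "ACYPI49694"],
        )
        st_ = ShareTable(per_library=pea, per_condition=pea)
        total = family_share(st_, pea.index)
        assert total["oviparae"] == 10.59
        assert total["viviparae"] == 0.02
        assert total["males"] == 0.02

    def test_family_share_empty_and_full(self):
        cm = make_cm({"L1": [10, 30, 60]})
        st_ = compute_shares(cm)
        assert (family_share(st_, []) == 0).all()
        assert np.allclose(family_share(st_, ["c0", "c1", "c2"]), 100.0)

    def test_family_share_unknown_member(self):
        cm = make_cm({"L1": [10, 90]})
        with pytest.raises(UnknownIdError):
            family_share(compute_shares(cm), ["nope"])


class TestSizeFactors:
    def test_identical_libraries_unit_factors(self):
        cm = make_cm({"L1": [5, 10, 20], "L2": [5, 10, 20]})
        assert np.allclose(size_factors(cm), [1.0, 1.0])

    def test_doubled_library(self):
        cm = make_cm({"L1": [5, 10, 20], "L2": [10, 20, 40]})
        sf = size_factors(cm)
        assert np.allclose(sf, [1 / np.sqrt(2), np.sqrt(2)])

    def test_global_scale_invariance(self, rng):
        # scaling every count by 7 scales each per-contig geometric mean by 7
        # as well, so the median of ratios is unchanged
        counts = {f"L{j}": rng.integers(1, 200, size=30) for j in range(3)}
        sf1 = size_factors(make_cm(counts))
        sf7 = size_factors(make_cm({k: 7 * v for k, v in counts.items()}))
        assert np.allclose(sf7, sf1)

    def test_contig_permutation_invariance(self, rng):
        counts = pd.DataFrame({f"L{j}": rng.integers(1, 200, size=30) for j in range(3)})
        counts.index = [f"c{i}" for i in range(30)]
        perm = counts.sample(frac=1, random_state=0)
        assert np.allclose(size_factors(CountMatrix(counts)),
                           size_factors(CountMatrix(perm)))

    def test_no_all_nonzero_contig_raises(self):
        cm = make_cm({"L1": [0, 5], "L2": [5, 0]})
        with pytest.raises(NormalizationError):
            size_factors(cm)

    def test_matches_pydeseq2_reference(self, rng):
        pydeseq2_pp = pytest.importorskip("pydeseq2.preprocessing")
        # odd contig count: the median picks a single element, so the two
        # formulations (median of ratios vs exp of median log-ratio) coincide
        counts = rng.negative_binomial(5, 0.1, size=(201, 4)) + 1
        cm = make_cm({f"L{j}": counts[:, j] for j in range(4)})
        _, ref = pydeseq2_pp.deseq2_norm(counts.T)
        assert np.allclose(size_factors(cm).to_numpy(), ref, rtol=1e-9)


class TestBHAdjust:
    def test_worked_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_and_degenerate(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ParameterError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=200))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_matches_bruteforce_oracle(self, pvals):
        adj = bh_adjust(pvals)
        assert np.allclose(adj, bh_bruteforce(pvals))
        assert (adj >= np.asarray(pvals) - 1e-12).all()
        assert (adj <= 1.0).all()


class TestClassifyBias:
    @pytest.mark.parametrize(
        "padj,lfc,expected",
        [
            (0.001, 2.3, "RA_biased"),
            (0.001, -2.3, "GA_biased"),
            (1.0, 0.0, "unbiased"),
            (0.03, 2.0, "ambiguous"),      # between the two p cutoffs
            (0.01, 2.0, "ambiguous"),      # boundary padj is not < 0.01
            (0.001, 1.0, "ambiguous"),     # boundary lfc is not > 1
            (0.06, 1.0, "ambiguous"),      # |lfc| not < 1
            (np.nan, 0.0, "ambiguous"),    # untested
        ],
    )
    def test_rules(self, padj, lfc, expected):
        assert classify_bias(padj, lfc) == expected


class TestNBDETest:
    def null_cm(self, seed, n=2000):
        from phyllopipe.redundancy import Contig
        from phyllopipe.simulate import SimSpec, gen_counts

        spec = SimSpec(seed=seed, de_fraction=0.0, dispersion=0.05,
                       highshare_family_size=0)
        contigs = [Contig(f"c{i:05d}", "A") for i in range(n)]
        cm, truth = gen_counts(spec, contigs)
        return cm, truth

    def test_constant_contig_null(self):
        cm = make_cm(
            {"GA_1": [50, 10], "GA_2": [50, 10], "RA_1": [50, 10], "RA_2": [50, 10]},
            {"GA_1": "GA", "GA_2": "GA", "RA_1": "RA", "RA_2": "RA"},
        )
        de = nb_de_test(cm)
        assert de.loc["c0", "log2fc"] == pytest.approx(0.0, abs=1e-12)
        assert de.loc["c0", "p"] == pytest.approx(1.0)

    def test_design_with_single_replicate_rejected(self):
        cm = make_cm({"GA_1": [5, 6], "RA_1": [5, 6], "RA_2": [7, 8]},
                     {"GA_1": "GA", "RA_1": "RA", "RA_2": "RA"})
        with pytest.raises(DesignError):
            nb_de_test(cm)

    def test_all_zero_contig_flagged_not_dropped(self):
        cm = make_cm(
            {"GA_1": [50, 0], "GA_2": [60, 0], "RA_1": [40, 0], "RA_2": [55, 0],
             "EGG_1": [10, 5]},
            {"GA_1": "GA", "GA_2": "GA", "RA_1": "RA", "RA_2": "RA", "EGG_1": "EGG"},
        )
        de = nb_de_test(cm)
        assert not de.loc["c1", "tested"]
        assert de.loc["c1", "bias"] == "ambiguous"
        assert np.isnan(de.loc["c1", "padj"])
        assert len(de) == 2

    def test_bias_classes_partition_tested(self):
        cm, _ = self.null_cm(0)
        de = nb_de_test(cm)
        counts = de.loc[de["tested"], "bias"].value_counts()
        assert counts.sum() == de["tested"].sum()

    def test_null_type_one_error_controlled(self):
        fractions = []
        for seed in range(3):
            cm, _ = self.null_cm(seed)
            de = nb_de_test(cm)
            fractions.append((de.loc[de["tested"], "padj"] < 0.01).mean())
        assert max(fractions) <= 0.02

    def test_planted_fold_change_detected_with_correct_sign(self):
        from phyllopipe.redundancy import Contig
        from phyllopipe.simulate import SimSpec, gen_counts

        spec = SimSpec(seed=5, de_fraction=0.3, de_log2fc=2.0, dispersion=0.05,
                       depth=2_000_000, highshare_family_size=0)
        contigs = [Contig(f"c{i:05d}", "A") for i in range(2000)]
        cm, truth = gen_counts(spec, contigs)
        de = nb_de_test(cm)
        truth = truth.set_index("contig_id")
        planted = truth["is_de"] & (de["base_mean"] >= 100)
        detected = de["bias"].isin(["RA_biased", "GA_biased"])
        assert detected[planted].mean() >= 0.8
        det_ids = de.index[detected & truth["is_de"]]
        signs_agree = np.sign(de.loc[det_ids, "log2fc"]) == np.sign(
            truth.loc[det_ids, "true_log2fc"]
        )
        assert signs_agree.mean() >= 0.99

    def test_padj_never_below_p(self):
        cm, _ = self.null_cm(1, n=500)
        de = nb_de_test(cm)
        tested = de[de["tested"]]
        assert (tested["padj"] >= tested["p"] - 1e-12).all()
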