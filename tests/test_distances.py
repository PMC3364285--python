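"""K2P distances, divergence summaries, pair classification and score utilities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from intetax import (
    DistanceMatrix,
    LabeledAlignment,
    aicc,
    at_content,
    classify_reference_pairs,
    distance_matrix,
    five_number_summary,
    group_divergence_summary,
    k2p_distance,
    rank_sum_compare,
)
from intetax.distances import is_binomial

BASES = "ACGT"


def random_seq_pair(rng, n=60, p_diff=0.2):
    a = rng.choice(list(BASES), n)
    b = a.copy()
    flip = rng.random(n) < p_diff
    for i in np.nonzero(flip)[0]:
        b[i] = rng.choice([c for c in BASES if c != a[i]])
    return "".join(a), "".join(b)


class TestK2P:
    def test_identical_sequences_have_zero_distance(self):
        assert k2p_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_closed_form_on_known_proportions(self):
        # 20 sites, 2 transitions (A<->G), 1 transversion (A<->C): P=0.1, Q=0.05
        a = "A" * 20
        b = "G" * 2 + "C" * 1 + "A" * 17
        expected = -0.5 * math.log(1 - 2 * 0.1 - 0.05) - 0.25 * math.log(1 - 2 * 0.05)
        assert k2p_distance(a, b) == pytest.approx(expected, abs=1e-12)
        assert round(k2p_distance(a, b), 4) == 0.1702

    def test_saturation_returns_infinite_flagged_distance(self):
        # P = 0.5, Q = 0 -> 1 - 2P - Q = 0: log undefined
        a = "A" * 10
        b = "G" * 5 + "A" * 5
        assert math.isinf(k2p_distance(a, b))

    def test_no_comparable_sites_is_an_error(self):
        with pytest.raises(ValueError):
            k2p_distance("--NN", "AC--")

    def test_pairwise_deletion_ignores_gaps_and_ambiguity(self):
        # 'AAT-CG' vs 'AATNCG': comparable sites are the 5 unambiguous pairs
        assert k2p_distance("AAT-CG", "AATNCG") == 0.0

    def test_k2p_at_least_raw_difference(self, rng):
        """Jensen-type bound: the corrected distance >= observed p-distance."""
        for _ in range(50):
            a, b = random_seq_pair(rng)
            d = k2p_distance(a, b)
            p_raw = sum(x != y for x, y in zip(a, b)) / len(a)
            if math.isfinite(d):
                assert d >= p_raw - 1e-12


class TestDistanceMatrix:
    def test_two_identical_sequences(self):
        aln = LabeledAlignment(["a", "b"], ["g", "g"], ["ACGT", "ACGT"])
        dm = distance_matrix(aln)
        assert np.allclose(dm.values, 0.0)

    def test_matches_per_pair_oracle_and_is_symmetric(self, rng):
        seqs = ["".join(rng.choice(list(BASES), 40)) for _ in range(6)]
        aln = LabeledAlignment([f"s{i}" for i in range(6)], ["g"] * 6, seqs)
        dm = distance_matrix(aln)
        assert np.array_equal(dm.values, dm.values.T)
        for i in range(6):
            for j in range(i + 1, 6):
                assert dm.values[i, j] == pytest.approx(
                    k2p_distance(seqs[i], seqs[j]), abs=1e-12
                )

    def test_row_order_follows_input_ids(self, default_dataset):
        *_, aln = default_dataset
        dm = distance_matrix(aln)
        assert dm.ids == aln.ids


class TestGroupDivergence:
    def test_hand_built_two_group_means(self):
        ids = ["a1", "a2", "b1", "b2"]
        vals = np.array(
            [
                [0.0, 0.02, 0.10, 0.12],
                [0.02, 0.0, 0.11, 0.13],
                [0.10, 0.11, 0.0, 0.04],
                [0.12, 0.13, 0.04, 0.0],
            ]
        )
        dm = DistanceMatrix(ids, vals)
        out = group_divergence_summary(dm, ["A", "A", "B", "B"])
        overall_w = out[(out.scope == "overall") & (out["class"] == "within")]
        overall_b = out[(out.scope == "overall") & (out["class"] == "between")]
        assert overall_w["mean"].iloc[0] == pytest.approx((0.02 + 0.04) / 2)
        assert overall_b["mean"].iloc[0] == pytest.approx(np.mean([0.10, 0.12, 0.11, 0.13]))

    def test_single_group_between_absent_not_zero(self):
        aln = LabeledAlignment(["a", "b"], ["g", "g"], ["ACGT", "ACGT"])
        out = group_divergence_summary(distance_matrix(aln), aln.labels)
        between = out[(out.scope == "overall") & (out["class"] == "between")]
        assert between["n_pairs"].iloc[0] == 0
        assert math.isnan(between["mean"].iloc[0])

    def test_simulated_clades_between_exceeds_within(self, default_dataset):
        *_, aln = default_dataset
        out = group_divergence_summary(distance_matrix(aln), aln.labels)
        w = out[(out.scope == "overall") & (out["class"] == "within")]["mean"].iloc[0]
        b = out[(out.scope == "overall") & (out["class"] == "between")]["median"].iloc[0]
        assert b > w


class TestReferencePairs:
    @pytest.fixture()
    def library(self):
        seqs = ["ACGTACGTAC", "ACGTACGTAC", "ACGTACGGAC", "TTGTACGTAC", "ACGAACGTAC"]
        labels = [
            "Encyrtus sasakii",
            "Encyrtus sasakii",
            "Encyrtus aurantii",
            "Copidosoma floridanum",
            "Encyrtus sp.",
        ]
        return LabeledAlignment([f"r{i}" for i in range(5)], labels, seqs)

    def test_pair_classes(self, library):
        out = classify_reference_pairs(library)
        classes = {
            tuple(sorted((r.id_a, r.id_b))): r["class"] for _, r in out.iterrows()
        }
        assert classes[("r0", "r1")] == "intraspecific"
        assert classes[("r0", "r2")] == "congeneric"
        assert classes[("r0", "r3")] == "other"

    def test_non_binomial_labels_excluded_and_counted(self, library):
        out = classify_reference_pairs(library)
        assert not out.id_a.str.contains("r4").any()
        assert not out.id_b.str.contains("r4").any()
        assert out.attrs["n_excluded"] == 1

    def test_class_counts_invariant_to_input_order(self, library):
        out1 = classify_reference_pairs(library)
        rev = LabeledAlignment(
            library.ids[::-1], library.labels[::-1], library.seqs[::-1]
        )
        out2 = classify_reference_pairs(rev)
        assert out1["class"].value_counts().to_dict() == out2["class"].value_counts().to_dict()

    @pytest.mark.parametrize(
        "label,ok",
        [
            ("Encyrtus sasakii", True),
            ("Encyrtus sp.", False),
            ("encyrtus sasakii", False),
            ("Encyrtus", False),
            ("Encyrtus cf. sasakii", False),
        ],
    )
    def test_binomial_regex(self, label, ok):
        assert is_binomial(label) is ok


class TestRankSum:
    def test_small_sample_exact_p(self):
        u, p = rank_sum_compare([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(1 / 3, abs=1e-9)

    def test_identical_samples_p_one(self):
        _, p = rank_sum_compare([1.0, 1.0, 1.0], [1.0, 1.0])
        assert p == 1.0

    def test_large_shift_highly_significant(self, rng):
        a = rng.normal(10.0, 1.0, 30)
        b = rng.normal(0.0, 1.0, 30)
        _, p = rank_sum_compare(a, b)
        assert p < 1e-3


class TestComposition:
    @pytest.mark.parametrize(
        "seq,expected", [("ATAT", 1.0), ("ACGT", 0.5), ("AAT-CG", 0.6)]
    )
    def test_at_content(self, seq, expected):
        assert at_content(seq) == pytest.approx(expected)

    def test_no_unambiguous_bases_is_error(self):
        with pytest.raises(ValueError):
            at_content("NN--")


class TestAicc:
    def test_hand_evaluation(self):
        assert aicc(-5, 2, 10) == pytest.approx(10 + 4 + 12 / 7, abs=1e-9)

    def test_limits_to_aic_for_large_n(self):
        assert aicc(-100, 5, 10**9) == pytest.approx(210.0, abs=1e-6)

    def test_undefined_when_n_too_small(self):
        with pytest.raises(ValueError):
            aicc(-5, 9, 10)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.lists(st.floats(-50, 50), min_size=1, max_size=40))
def test_five_number_summary_brackets_data(values):
    s = five_number_summary(values)
    assert s["min"] <= s["q1"] <= s["median"] <= s["q3"] <= s["max"]
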