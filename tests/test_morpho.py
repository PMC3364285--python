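"""Landmark I/O, Procrustes superimposition, relative warps, ANOVA, clustering."""

import numpy as np
import pytest

from intetax import (
    LandmarkSet,
    Partition,
    SimConfig,
    anova_by_axis,
    average_replicates,
    cluster_specimens,
    gpa,
    read_tps,
    relative_warps,
    simulate_landmarks,
    simulate_species_tree,
    write_tps,
)

TRIANGLE = np.array([[0.0, 0.0], [1.0, 0.0], [0.3, 0.8]])


def random_similarity(rng, conf):
    theta = rng.uniform(0, 2 * np.pi)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    return rng.uniform(0.3, 3.0) * conf @ rot.T + rng.uniform(-5, 5, 2)


@pytest.fixture(scope="module")
def wing_set():
    cfg = SimConfig(seed=21)
    _, part = simulate_species_tree(cfg)
    return part, simulate_landmarks(part, cfg)


class TestTPS:
    def test_minimal_file_parses(self, tmp_path):
        p = tmp_path / "one.tps"
        p.write_text(
            "LM=7\n" + "\n".join(f"{i}.0 {i + 1}.0" for i in range(7)) + "\nID=w1\n"
        )
        lset = read_tps(p)
        assert lset.coords.shape == (1, 7, 2)
        assert lset.specimen_ids == ["w1"]

    def test_round_trip_identity(self, tmp_path, wing_set):
        _, lset = wing_set
        p = tmp_path / "wings.tps"
        write_tps(lset, p)
        back = read_tps(p)
        assert back.specimen_ids == lset.specimen_ids
        assert back.replicates == lset.replicates
        assert np.array_equal(back.coords, lset.coords)

    def test_landmark_count_mismatch_errors_with_block_index(self, tmp_path):
        p = tmp_path / "bad.tps"
        p.write_text(
            "LM=2\n0 0\n1 1\nID=a\nLM=3\n0 0\n1 1\n2 2\nID=b\n"
        )
        with pytest.raises(ValueError, match="block 1"):
            read_tps(p)


class TestReplicates:
    def test_identical_replicates_unchanged(self):
        coords = np.stack([TRIANGLE, TRIANGLE])
        lset = LandmarkSet(coords, ["s1", "s1"], [0, 1])
        out = average_replicates(lset)
        assert np.allclose(out.coords[0], TRIANGLE)

    def test_midpoint_of_two_replicates(self):
        coords = np.stack([np.zeros((3, 2)), np.full((3, 2), 2.0)])
        out = average_replicates(LandmarkSet(coords, ["s", "s"], [0, 1]))
        assert np.allclose(out.coords[0], 1.0)

    def test_averaging_reduces_replicate_noise(self, rng):
        true = TRIANGLE
        reps = np.stack([true + rng.normal(0, 0.05, true.shape) for _ in range(40)])
        ids = [f"s{i // 2}" for i in range(40)]
        averaged = average_replicates(LandmarkSet(reps, ids, [i % 2 for i in range(40)]))
        var_raw = np.var(reps - true)
        var_avg = np.var(averaged.coords - true)
        assert var_avg < var_raw

    def test_replicates_closer_within_than_between_specimens(self, wing_set):
        _, lset = wing_set
        ids = np.array(lset.specimen_ids)
        within, between = [], []
        for i in range(len(lset)):
            for j in range(i + 1, len(lset)):
                d = np.linalg.norm(lset.coords[i] - lset.coords[j])
                (within if ids[i] == ids[j] else between).append(d)
        assert np.mean(within) < np.mean(between)


class TestGPA:
    def test_similarity_transformed_copies_collapse_to_consensus(self, rng):
        confs = np.stack([random_similarity(rng, TRIANGLE) for _ in range(8)])
        aligned, consensus = gpa(confs)
        for a in aligned:
            assert np.allclose(a, consensus, atol=1e-8)

    def test_output_invariant_to_similarity_transforms(self, rng):
        base = np.stack(
            [TRIANGLE + rng.normal(0, 0.05, TRIANGLE.shape) for _ in range(6)]
        )
        transformed = np.stack([random_similarity(rng, c) for c in base])
        a1, c1 = gpa(base)
        a2, c2 = gpa(transformed)
        assert np.allclose(c1, c2, atol=1e-8)
        assert np.allclose(a1, a2, atol=1e-8)

    def test_mirror_images_are_not_identified(self):
        mirrored = TRIANGLE * np.array([1.0, -1.0])
        aligned, _ = gpa(np.stack([TRIANGLE, mirrored]))
        assert np.linalg.norm(aligned[0] - aligned[1]) > 0.1

    def test_idempotent(self, rng):
        base = np.stack(
            [TRIANGLE + rng.normal(0, 0.05, TRIANGLE.shape) for _ in range(5)]
        )
        a1, _ = gpa(base)
        a2, _ = gpa(a1)
        assert np.allclose(a1, a2, atol=1e-8)

    def test_degenerate_configuration_rejected(self):
        with pytest.raises(ValueError):
            gpa(np.zeros((3, 4, 2)))


class TestRelativeWarps:
    def test_identical_shapes_give_zero_scores(self):
        aligned = np.stack([TRIANGLE] * 5)
        w = relative_warps(aligned)
        assert np.allclose(w.scores, 0.0)
        assert np.allclose(w.variance_fractions, 0.0)

    def test_matches_eigendecomposition_oracle(self, rng):
        aligned = np.stack(
            [TRIANGLE + rng.normal(0, 0.1, TRIANGLE.shape) for _ in range(12)]
        )
        w = relative_warps(aligned)
        flat = aligned.reshape(12, -1)
        cov = np.cov(flat.T, bias=True)
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eigvals = eigvals[eigvals > 1e-12 * eigvals[0]]
        expected = eigvals / eigvals.sum()
        assert np.allclose(w.variance_fractions[: len(expected)], expected, atol=1e-9)

    def test_variance_fractions_sum_to_one_and_components_orthonormal(self, rng):
        aligned = np.stack(
            [TRIANGLE + rng.normal(0, 0.1, TRIANGLE.shape) for _ in range(10)]
        )
        w = relative_warps(aligned)
        assert w.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)
        gram = w.components @ w.components.T
        assert np.allclose(gram, np.eye(len(gram)), atol=1e-8)

    def test_common_rotation_leaves_variance_fractions_unchanged(self, rng):
        aligned = np.stack(
            [TRIANGLE + rng.normal(0, 0.1, TRIANGLE.shape) for _ in range(10)]
        )
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        rotated = aligned @ rot.T
        w1 = relative_warps(aligned)
        w2 = relative_warps(rotated)
        assert np.allclose(w1.variance_fractions, w2.variance_fractions, atol=1e-9)

    def test_group_separation_visible_on_first_warp(self, rng):
        g1 = np.stack([TRIANGLE + rng.normal(0, 0.02, TRIANGLE.shape) for _ in range(6)])
        g2 = np.stack(
            [TRIANGLE + 0.3 + np.array([[0.2, 0], [0, 0], [0, 0]]) + rng.normal(0, 0.02, TRIANGLE.shape) for _ in range(6)]
        )
        aligned, _ = gpa(np.concatenate([g1, g2]))
        w = relative_warps(aligned)
        s1, s2 = w.scores[:6, 0], w.scores[6:, 0]
        assert abs(s1.mean() - s2.mean()) > 3 * (s1.std() + s2.std())


class TestANOVA:
    def test_hand_computed_f(self):
        scores = np.array([0.0, 1.0, 2.0, 3.0])
        out = anova_by_axis(scores, ["a", "a", "b", "b"], axes=1)
        assert out.F.iloc[0] == pytest.approx(8.0)
        assert (out.df_between.iloc[0], out.df_within.iloc[0]) == (1, 2)

    def test_agrees_with_scipy_f_oneway(self, rng):
        from scipy.stats import f_oneway

        x = rng.normal(0, 1, 30)
        labels = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        out = anova_by_axis(x, labels, axes=1)
        ref = f_oneway(x[:10], x[10:20], x[20:])
        assert out.F.iloc[0] == pytest.approx(ref.statistic)
        assert out.p.iloc[0] == pytest.approx(ref.pvalue)

    def test_null_f_near_one_in_expectation(self, rng):
        fs = []
        for _ in range(200):
            x = rng.normal(0, 1, 18)
            fs.append(anova_by_axis(x, ["a", "b", "c"] * 6, axes=1).F.iloc[0])
        assert np.mean(fs) == pytest.approx(1.0, abs=0.25)

    def test_zero_within_variance_reports_infinite_f(self):
        scores = np.array([0.0, 0.0, 1.0, 1.0])
        out = anova_by_axis(scores, ["a", "a", "b", "b"], axes=1)
        assert np.isinf(out.F.iloc[0])
        assert out.p.iloc[0] == 0.0


class TestClustering:
    def test_k_one_single_block(self, rng):
        scores = rng.normal(0, 1, (8, 3))
        part = cluster_specimens(scores, k=1, n_axes=3)
        assert part.n_blocks == 1

    def test_recovers_synthetic_wing_groups(self, wing_set):
        part, lset = wing_set
        averaged = average_replicates(lset)
        aligned, cons = gpa(averaged)
        warps = relative_warps(aligned, specimen_ids=averaged.specimen_ids,
                               consensus=cons)
        clusters = cluster_specimens(warps, k=3, n_axes=10)
        truth = Partition(dict(part.assignment))
        assert truth.ari(clusters) == pytest.approx(1.0)

    def test_duplicated_specimen_stays_with_its_copy(self, rng):
        scores = rng.normal(0, 1, (6, 4))
        scores = np.vstack([scores, scores[0]])
        part = cluster_specimens(scores, k=3, n_axes=4,
                                 specimen_ids=[f"s{i}" for i in range(7)])
        assert part.assignment["s0"] == part.assignment["s6"]

    def test_k_exceeding_specimens_is_error(self, rng):
        with pytest.raises(ValueError):
            cluster_specimens(rng.normal(0, 1, (4, 2)), k=5)
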