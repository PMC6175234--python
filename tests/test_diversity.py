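"""Rarefaction, alpha diversity, Bray-Curtis and PCoA."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from necrosip.diversity import (
    DistanceMatrix,
    alpha_diversity,
    bray_curtis,
    pcoa,
    rarefied_alpha_diversity,
    rarefy,
)
from necrosip.io import CountTable, ValidationError
from oracles import bray_curtis_pair, expected_rarefied_richness


def table_from(values, samples=None):
    values = np.atleast_2d(values)
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=[f"p{i}" for i in range(values.shape[0])],
                      columns=samples)
    return CountTable(df)


class TestRarefy:
    def test_exact_depth_sample_returned_unchanged(self):
        table = table_from([[5], [3], [2]])
        (_, sub, _), = rarefy(table, depth=10, n_resamples=1, seed=0)
        pd.testing.assert_frame_equal(sub.counts, table.counts)

    def test_columns_sum_exactly_to_depth_and_shallow_samples_reported(self):
        rng = np.random.default_rng(1)
        table = table_from(rng.integers(0, 60, size=(40, 4)))
        depth = int(table.sample_depths().sort_values().iloc[1])  # excludes min
        for _, sub, excluded in rarefy(table, depth, n_resamples=3, seed=2):
            assert (sub.sample_depths() == depth).all()
            assert excluded == [
                s for s in table.sample_ids if table.sample_depths()[s] < depth
            ]

    def test_mean_observed_richness_matches_closed_form(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 40, size=60)
        counts[counts < 5] = 0  # mix of absent, rare and common
        table = table_from(counts[:, None])
        depth = 200
        richness = [
            float((sub.counts.iloc[:, 0] > 0).sum())
            for _, sub, _ in rarefy(table, depth, n_resamples=300, seed=4)
        ]
        expected = expected_rarefied_richness(counts, depth)
        se = np.std(richness, ddof=1) / np.sqrt(len(richness))
        assert np.mean(richness) == pytest.approx(expected, abs=max(4 * se, 0.5))

    def test_reproducible_under_fixed_seed(self):
        table = table_from(np.random.default_rng(5).integers(0, 30, size=(20, 3)))
        runs = []
        for _ in range(2):
            runs.append([sub.counts for _, sub, _ in rarefy(table, 50, 3, seed=9)])
        for a, b in zip(*runs):
            pd.testing.assert_frame_equal(a, b)

    def test_permutation_equivariant_in_phylotype_order(self):
        rng = np.random.default_rng(6)
        df = table_from(rng.integers(0, 30, size=(15, 2))).counts
        perm = rng.permutation(df.index)
        (_, sub1, _), = rarefy(CountTable(df), 40, 1, seed=11)
        (_, sub2, _), = rarefy(CountTable(df.loc[perm]), 40, 1, seed=11)
        # same seed, same per-sample draws: totals agree, marginals close
        assert (sub1.sample_depths() == sub2.sample_depths()).all()

    def test_invalid_depth_rejected(self):
        with pytest.raises(ValidationError):
            list(rarefy(table_from([[5], [5]]), depth=0))


class TestAlphaDiversity:
    def test_uniform_community(self):
        metrics = alpha_diversity([10, 10, 10, 10])
        assert metrics["observed_phylotypes"] == 4
        assert metrics["shannon"] == pytest.approx(np.log(4))

    def test_single_phylotype(self):
        metrics = alpha_diversity([100])
        assert metrics["observed_phylotypes"] == 1
        assert metrics["shannon"] == 0.0

    def test_entropy_bounded_by_log_richness(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            counts = rng.integers(0, 50, size=30)
            if counts.sum() == 0:
                continue
            metrics = alpha_diversity(counts)
            assert metrics["shannon"] <= np.log(metrics["observed_phylotypes"]) + 1e-12

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValidationError):
            alpha_diversity([0, 0])

    def test_rarefied_summary_runs_per_sample(self):
        rng = np.random.default_rng(8)
        table = table_from(rng.integers(0, 100, size=(30, 3)))
        df = rarefied_alpha_diversity(table, depth=300, n_resamples=10, seed=1)
        assert set(df["sample_id"]) <= set(table.sample_ids)
        assert (df["observed_phylotypes"] > 0).all()


class TestBrayCurtis:
    def test_identical_columns_distance_zero(self):
        d = bray_curtis(table_from([[3, 3], [1, 1]]))
        assert d.values[0, 1] == 0.0

    def test_disjoint_supports_distance_one(self):
        d = bray_curtis(table_from([[5, 0], [0, 7]]))
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_hand_computed_three_column_case(self):
        df = pd.DataFrame({"a": [1.0, 0.0], "b": [0.0, 1.0], "c": [0.5, 0.5]})
        d = bray_curtis(df)
        assert d.values[0, 2] == pytest.approx(0.5)
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_matches_direct_formula_and_proportion_invariance(self):
        rng = np.random.default_rng(9)
        counts = rng.integers(0, 50, size=(25, 4))
        counts[0] += 1
        # equalize depths so counts and proportions give identical distances
        depth = counts.sum(axis=0).max()
        for j in range(4):
            counts[0, j] += depth - counts[:, j].sum()
        d_counts = bray_curtis(table_from(counts))
        props = counts / counts.sum(axis=0)
        d_props = bray_curtis(pd.DataFrame(props, columns=d_counts.sample_ids))
        np.testing.assert_allclose(d_counts.values, d_props.values, atol=1e-12)
        assert d_counts.values[1, 2] == pytest.approx(
            bray_curtis_pair(counts[:, 1], counts[:, 2])
        )


class TestPCoA:
    def euclid_dm(self, points):
        ids = [f"s{i}" for i in range(len(points))]
        return DistanceMatrix(ids, squareform(pdist(points)))

    def test_identical_samples_collapse_to_equal_coordinates(self):
        d = DistanceMatrix(["a", "b"], np.zeros((2, 2)))
        result = pcoa(d)
        assert result.coordinates.shape[1] == 0 or np.allclose(
            result.coordinates[0], result.coordinates[1]
        )

    @pytest.mark.parametrize("seed", [0, 1])
    def test_euclidean_distances_reconstructed(self, seed):
        rng = np.random.default_rng(seed)
        points = rng.normal(size=(8, 3))
        d = self.euclid_dm(points)
        result = pcoa(d)
        reconstructed = squareform(pdist(result.coordinates))
        np.testing.assert_allclose(reconstructed, d.values, atol=1e-8)

    def test_collinear_points_recover_line_geometry(self):
        points = np.array([[0.0], [1.0], [3.0], [6.0]])
        result = pcoa(self.euclid_dm(points))
        axis1 = result.coordinates[:, 0]
        np.testing.assert_allclose(
            np.abs(np.subtract.outer(axis1, axis1)),
            self.euclid_dm(points).values,
            atol=1e-8,
        )

    def test_embedding_never_exceeds_input_distances_when_psd(self):
        rng = np.random.default_rng(2)
        points = rng.normal(size=(6, 2))
        d = self.euclid_dm(points)
        result = pcoa(d)
        emb = squareform(pdist(result.coordinates))
        assert np.all(emb <= d.values + 1e-8)

    def test_matches_skbio_reference(self):
        import skbio

        rng = np.random.default_rng(4)
        counts = rng.integers(0, 80, size=(40, 6))
        counts[0] += 1
        d = bray_curtis(table_from(counts))
        mine = pcoa(d)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d.values, ids=d.sample_ids)
        )
        n_pos = mine.coordinates.shape[1]
        np.testing.assert_allclose(
            np.sort(mine.eigenvalues[:n_pos]),
            np.sort(np.asarray(ref.eigvals)[np.asarray(ref.eigvals) > 1e-9]),
            rtol=1e-6, atol=1e-9,
        )
        np.testing.assert_allclose(
            np.abs(mine.coordinates[:, 0]),
            np.abs(ref.samples.iloc[:, 0].to_numpy()),
            atol=1e-6,
        )

    def test_negative_eigenvalues_reported_but_axes_dropped(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 8, size=(15, 10))  # sparse -> non-Euclidean
        counts[0] += 1
        result = pcoa(bray_curtis(table_from(counts)))
        assert (result.eigenvalues < -1e-12).any()  # Bray-Curtis is non-Euclidean
        assert result.coordinates.shape[1] == (
            result.eigenvalues > result.eigenvalues.max() * 1e-12
        ).sum()

    def test_cailliez_correction_makes_matrix_embeddable(self):
        rng = np.random.default_rng(6)
        counts = rng.integers(0, 8, size=(15, 10))
        counts[0] += 1
        d = bray_curtis(table_from(counts))
        corrected = pcoa(d, correction="cailliez")
        assert (corrected.eigenvalues >= -1e-6).all()

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValidationError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [0.5, 0.0]]))
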