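"""PCA SNP-weights model: normalization, fitting, projection, proportions."""

from __future__ import annotations

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from breedcomp import (
    BreedCentroids,
    estimate_proportions,
    fit_reference,
    load_weights,
    normalize,
    project,
    save_weights,
    self_assign,
)
from breedcomp.genotype_io import MISSING, GenotypeTable, MarkerRecord, SampleRecord


def simplex_grid_nearest(centroids: np.ndarray, score: np.ndarray, step=0.001):
    """Brute-force oracle: nearest point to ``score`` among simplex grid
    combinations of K=3 centroid rows (independent of the linear solver)."""
    assert centroids.shape[0] == 3
    a1 = np.arange(0.0, 1.0 + step / 2, step)
    g1, g2 = np.meshgrid(a1, a1, indexing="ij")
    mask = g1 + g2 <= 1.0 + 1e-12
    w = np.stack([g1[mask], g2[mask], 1.0 - g1[mask] - g2[mask]], axis=1)
    pts = w @ centroids
    d = ((pts - score) ** 2).sum(axis=1)
    return w[np.argmin(d)]


class TestNormalize:
    def test_dosage_at_twice_freq_centers_to_zero(self):
        x = normalize(np.array([[1]]), np.array([0.5]))
        assert x[0, 0] == 0.0

    def test_half_freq_homozygote_is_sqrt_two(self):
        # (2 - 2*0.5) / sqrt(2*0.5*0.5) = 1 / sqrt(0.5) = sqrt(2)
        x = normalize(np.array([[2]]), np.array([0.5]))
        assert x[0, 0] == pytest.approx(np.sqrt(2.0))

    def test_missing_imputes_to_zero(self):
        x = normalize(np.array([[MISSING, MISSING]]), np.array([0.2, 0.9]))
        np.testing.assert_array_equal(x, [[0.0, 0.0]])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="frequencies"):
            normalize(np.zeros((1, 3)), np.array([0.5]))

    def test_boundary_frequency_rejected(self):
        with pytest.raises(ValueError):
            normalize(np.zeros((1, 1)), np.array([0.0]))


class TestFitReference:
    def test_opposite_fixed_breeds_separate_on_axis1(self, opposite_breeds_table):
        model, cents = fit_reference(opposite_breeds_table, shrinkage=False)
        scores = model.ref_scores[:, 0]
        a, b = scores[:3], scores[3:]
        # two tight clusters, centroids equal magnitude and opposite sign
        assert np.sign(a).min() == np.sign(a).max() != np.sign(b).max()
        assert abs(a.mean() + b.mean()) < 1e-10
        assert np.allclose(cents.coords[0], -cents.coords[1])

    def test_trace_bounds_retained_eigenvalues(self, small_panel):
        panel, _, _ = small_panel
        model, _ = fit_reference(panel.table, shrinkage=False)
        assert model.trace >= model.eigenvalues.sum() - 1e-9
        # retaining the full rank recovers the whole trace
        full, _ = fit_reference(panel.table, n_axes=panel.table.n_samples - 1,
                                shrinkage=False)
        assert full.trace == pytest.approx(full.eigenvalues.sum(), rel=1e-8)

    def test_in_sample_projection_reproduces_scores(self, small_panel):
        panel, _, _ = small_panel
        model, _ = fit_reference(panel.table, shrinkage=False)
        keep = set(model.marker_names)
        cols = [j for j, m in enumerate(panel.table.markers) if m.name in keep]
        X = normalize(panel.table.calls[:, cols], model.allele_freqs)
        np.testing.assert_allclose(X @ model.snp_weights, model.ref_scores,
                                   atol=1e-8)

    def test_breed_with_single_sample_rejected(self, toy_table):
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_reference(toy_table)

    def test_rank_deficiency_reports_achievable_rank(self):
        markers = [MarkerRecord(f"m{j}", "1", 10 + j, "A", "G") for j in range(4)]
        samples = [SampleRecord(f"s{i}", "ab"[i % 2]) for i in range(4)]
        calls = np.tile(np.array([[2, 0, 2, 0]], dtype=np.int8).T, (1, 1))
        calls = np.array([[2, 2, 2, 2], [0, 0, 0, 0], [2, 2, 2, 2], [0, 0, 0, 0]],
                         dtype=np.int8)
        table = GenotypeTable(markers, samples, calls)
        with pytest.raises(ValueError, match="rank"):
            fit_reference(table, n_axes=3, shrinkage=False)

    def test_monomorphic_markers_dropped_and_recorded(self):
        markers = [MarkerRecord("poly", "1", 10, "A", "G"),
                   MarkerRecord("mono", "1", 20, "A", "0")]
        samples = [SampleRecord(f"s{i}", "ab"[i % 2]) for i in range(4)]
        calls = np.array([[2, 2], [0, 2], [2, 2], [0, 2]], dtype=np.int8)
        model, _ = fit_reference(GenotypeTable(markers, samples, calls),
                                 shrinkage=False)
        assert model.dropped_markers == ["mono"]
        assert model.marker_names == ["poly"]

    def test_shrink_factors_at_least_one(self, study_model):
        model, _ = study_model
        assert (model.shrink >= 1.0).all()


class TestProject:
    def test_reference_sample_projects_to_its_scores(self, small_panel):
        panel, _, _ = small_panel
        model, _ = fit_reference(panel.table, shrinkage=False)
        proj = project(model, panel.table, apply_shrink=False)
        np.testing.assert_allclose(proj.scores, model.ref_scores, atol=1e-8)

    def test_exact_copy_target_lands_near_reference_scores(self, study_panel,
                                                           study_model):
        panel, _, _ = study_panel
        model, _ = study_model
        copy = panel.table.subset_samples([0])
        proj = project(model, copy)  # shrink applied
        ref_norm = np.linalg.norm(model.ref_scores[0])
        assert np.linalg.norm(proj.scores[0]) == pytest.approx(ref_norm, rel=0.10)

    def test_all_missing_target_scores_zero(self, small_panel):
        panel, _, _ = small_panel
        model, _ = fit_reference(panel.table, shrinkage=False)
        blank = GenotypeTable(
            list(panel.table.markers),
            [SampleRecord("blank", None)],
            np.full((1, panel.table.n_markers), MISSING, dtype=np.int8),
        )
        proj = project(model, blank)
        np.testing.assert_array_equal(proj.scores, 0.0)

    def test_too_few_overlapping_markers_rejected(self, small_panel):
        panel, _, _ = small_panel
        model, _ = fit_reference(panel.table, shrinkage=False)
        few = panel.table.subset_markers(model.marker_names[: len(model.markers) // 4])
        with pytest.raises(ValueError, match="unreliable"):
            project(model, few)

    def test_marker_order_permutation_invariant(self, small_panel):
        panel, _, _ = small_panel
        model, _ = fit_reference(panel.table, shrinkage=False)
        rng = np.random.default_rng(5)
        perm = rng.permutation(panel.table.n_markers)
        shuffled = panel.table.subset_markers(
            [panel.table.marker_names[j] for j in perm]
        )
        p1 = project(model, panel.table, apply_shrink=False)
        p2 = project(model, shuffled, apply_shrink=False)
        np.testing.assert_allclose(p1.scores, p2.scores, atol=1e-10)

    def test_absent_markers_reported_in_effective_count(self, small_panel):
        panel, _, _ = small_panel
        model, _ = fit_reference(panel.table, shrinkage=False)
        n = len(model.markers)
        sub = panel.table.subset_markers(model.marker_names[: int(n * 0.6)])
        proj = project(model, sub)
        assert proj.markers_used == int(n * 0.6)
        assert proj.markers_total == n


class TestEstimateProportions:
    CENTROIDS = BreedCentroids(
        ("x", "y", "z"),
        np.array([[1.0, 0.0], [-0.5, 0.9], [-0.5, -0.9]]),
    )

    def test_score_at_centroid_gives_unit_vector(self):
        est = estimate_proportions(self.CENTROIDS.coords[1], self.CENTROIDS)[0]
        np.testing.assert_allclose(est.proportions, [0, 1, 0], atol=1e-12)

    def test_two_breed_midpoint_is_half_half(self):
        cents = BreedCentroids(("x", "y"), np.array([[1.0], [-1.0]]))
        est = estimate_proportions(np.array([0.0]), cents)[0]
        np.testing.assert_allclose(est.proportions, [0.5, 0.5], atol=1e-12)

    def test_interior_combination_recovered_and_matches_grid(self):
        truth = np.array([0.2, 0.3, 0.5])
        score = truth @ self.CENTROIDS.coords
        est = estimate_proportions(score, self.CENTROIDS)[0]
        np.testing.assert_allclose(est.proportions, truth, atol=1e-6)
        oracle = simplex_grid_nearest(self.CENTROIDS.coords, score)
        assert np.abs(est.proportions - oracle).max() < 1e-3

    def test_coincident_centroids_rejected(self):
        bad = BreedCentroids(("x", "y", "z"),
                             np.array([[1.0, 0.0], [1.0, 0.0], [-1.0, 0.0]]))
        with pytest.raises(ValueError, match="singular"):
            estimate_proportions(np.array([0.0, 0.0]), bad)

    def test_axis_count_must_be_breeds_minus_one(self):
        cents = BreedCentroids(("x", "y"), np.array([[1.0, 0.0], [-1.0, 0.0]]))
        with pytest.raises(ValueError, match="K - 1"):
            estimate_proportions(np.array([0.0, 0.0]), cents)

    def test_raw_preserved_when_clipping(self):
        score = 1.6 * self.CENTROIDS.coords[0]  # outside the simplex hull
        est = estimate_proportions(score, self.CENTROIDS)[0]
        assert est.raw.min() < 0
        assert est.proportions.min() == 0.0
        assert est.proportions.sum() == pytest.approx(1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_estimates_always_on_simplex(self, seed):
        rng = np.random.default_rng(seed)
        score = rng.normal(scale=2.0, size=2)
        est = estimate_proportions(score, self.CENTROIDS)[0]
        assert (est.proportions >= 0).all()
        assert est.proportions.sum() == pytest.approx(1.0, abs=1e-9)


class TestSelfAssign:
    def test_perfectly_differentiated_breeds_assign_fully(self, opposite_breeds_table):
        model, cents = fit_reference(opposite_breeds_table, shrinkage=False)
        ests = self_assign(opposite_breeds_table, model, cents)
        for est, s in zip(ests, opposite_breeds_table.samples):
            assert est.proportion_for(s.breed) == pytest.approx(1.0, abs=1e-9)

    def test_own_breed_average_dominates(self, small_panel):
        panel, _, _ = small_panel
        model, cents = fit_reference(panel.table, shrinkage=False)
        ests = self_assign(panel.table, model, cents)
        registry = {s.id: s.breed for s in panel.table.samples}
        for breed in panel.table.breeds:
            members = [e for e in ests if registry[e.sample_id] == breed]
            mean_by_breed = np.mean([e.proportions for e in members], axis=0)
            assert cents.breeds[int(np.argmax(mean_by_breed))] == breed

    def test_planted_fifty_fifty_sample_splits_between_sources(self, small_panel):
        panel, haps, _ = small_panel
        table = panel.table
        # synthetic 50:50: one haplotype from a breed1 member, one from breed2
        i1 = next(i for i, s in enumerate(table.samples) if s.breed == "breed1")
        i2 = next(i for i, s in enumerate(table.samples) if s.breed == "breed2")
        admixed = (haps[i1, 0] + haps[i2, 1]).astype(np.int8)
        aug = GenotypeTable(
            list(table.markers),
            list(table.samples) + [SampleRecord("plant", "breed1")],
            np.vstack([table.calls, admixed[None, :]]),
        )
        model, cents = fit_reference(aug, shrinkage=False)
        est = self_assign(aug, model, cents)[-1]
        top2 = np.argsort(est.proportions)[-2:]
        assert {cents.breeds[t] for t in top2} == {"breed1", "breed2"}

    def test_wrong_panel_rejected(self, small_panel, opposite_breeds_table):
        panel, _, _ = small_panel
        model, cents = fit_reference(panel.table, shrinkage=False)
        with pytest.raises(ValueError, match="sample ids"):
            self_assign(opposite_breeds_table, model, cents)


class TestDifferentiationMonotonicity:
    def test_own_breed_proportion_increases_with_fst(self):
        from breedcomp import BNConfig, balding_nichols_panel

        means = []
        for fst in (0.01, 0.05, 0.2):
            cfg = BNConfig(n_breeds=3, n_per_breed=20, n_markers=400,
                           fst=fst, seed=21)
            panel, _, _ = balding_nichols_panel(cfg)
            model, cents = fit_reference(panel.table, shrinkage=False)
            ests = self_assign(panel.table, model, cents)
            registry = {s.id: s.breed for s in panel.table.samples}
            means.append(np.mean([e.proportion_for(registry[e.sample_id])
                                  for e in ests]))
        assert means[0] < means[1] < means[2]


class TestWeightsFile:
    def test_save_load_round_trip_preserves_projection(self, small_panel):
        panel, _, _ = small_panel
        model, cents = fit_reference(panel.table, shrinkage=False)
        buf = io.StringIO()
        save_weights(model, cents, buf)
        buf.seek(0)
        model2, cents2 = load_weights(buf)
        assert cents2.breeds == cents.breeds
        np.testing.assert_allclose(cents2.coords, cents.coords, atol=1e-9)
        p1 = project(model, panel.table, apply_shrink=False)
        p2 = project(model2, panel.table, apply_shrink=False)
        np.testing.assert_allclose(p1.scores, p2.scores, atol=1e-8)
        assert model2.trace == pytest.approx(model.trace)
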