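"""Discriminant model, cross-validation and unknown assignment."""

import numpy as np
import pytest
from scipy.linalg import cho_factor

import wingmorph as wm
from wingmorph.discriminant import DiscriminantModel, classify
from conftest import random_similarity


def manual_model(group_means, pooled, priors=None, level="group"):
    """Build a model directly in an identity reduced basis (for closed forms)."""
    group_means = np.asarray(group_means, dtype=float)
    g, d = group_means.shape
    priors = np.full(g, 1.0 / g) if priors is None else np.asarray(priors)
    return DiscriminantModel(
        grouping_level=level,
        groups=[f"g{i + 1}" for i in range(g)],
        priors=priors,
        n_per_group=np.full(g, 10),
        grand_mean=np.zeros(d),
        components=np.eye(d),
        group_means=group_means,
        pooled_cov=pooled,
        axes=np.zeros((d, 0)),
        axis_eigenvalues=np.zeros(0),
        _chol=cho_factor(pooled),
    )


def cross_pattern(center, scale=1.0):
    """Four points whose within-group covariance is exactly isotropic."""
    center = np.asarray(center, dtype=float)
    offsets = scale * np.array([[1, 0], [-1, 0], [0, 1], [0, -1]], dtype=float)
    return center + offsets


class TestFitLDA:
    def test_zero_within_variance_is_singular(self):
        x = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0], [5.0, 5.0]])
        with pytest.raises(wm.SingularCovarianceError):
            wm.fit_lda(x, ["a", "a", "b", "b"])

    def test_singleton_group_named(self):
        x = np.random.default_rng(0).normal(size=(5, 3))
        with pytest.raises(wm.ValidationError, match="lonely"):
            wm.fit_lda(x, ["a", "a", "a", "a", "lonely"])

    def test_isotropic_axis_parallel_to_mean_difference(self):
        # exact isotropic within-group scatter: the single canonical axis
        # must point along the (whitened = raw) mean difference
        mu_a = np.array([0.0, 0.0])
        mu_b = np.array([3.0, 4.0])
        x = np.vstack([cross_pattern(mu_a), cross_pattern(mu_b)])
        labels = ["a"] * 4 + ["b"] * 4
        model = wm.fit_lda(x, labels)
        assert model.axes.shape[1] == 1
        axis_full = model.axes[:, 0] @ model.components  # back to input space
        direction = (mu_b - mu_a) / np.linalg.norm(mu_b - mu_a)
        cosine = abs(np.dot(axis_full, direction) / np.linalg.norm(axis_full))
        assert np.arccos(min(cosine, 1.0)) < 1e-6

    def test_axis_count_bounded_by_groups(self, separable_aligned):
        _, _, aligned, groups = separable_aligned
        model = wm.fit_lda(aligned.tangent, groups)
        assert model.n_axes <= len(model.groups) - 1
        assert model.priors.sum() == pytest.approx(1.0, abs=1e-12)

    def test_proportional_priors_follow_counts(self):
        rng = np.random.default_rng(1)
        x = np.vstack([rng.normal(size=(6, 3)), rng.normal(5, 1, size=(3, 3))])
        model = wm.fit_lda(x, ["a"] * 6 + ["b"] * 3, priors_mode="proportional")
        np.testing.assert_allclose(model.priors, [2 / 3, 1 / 3])

    def test_pooled_covariance_positive_definite(self, separable_aligned):
        _, _, aligned, groups = separable_aligned
        model = wm.fit_lda(aligned.tangent, groups)
        np.testing.assert_allclose(model.pooled_cov, model.pooled_cov.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(model.pooled_cov) > 0)


class TestMahalanobisAndPosteriors:
    def test_distance_to_own_mean_is_zero(self):
        model = manual_model([[0, 0, 0], [4, 0, 0]], np.eye(3))
        md = wm.mahalanobis_to_groups(model, np.array([4.0, 0.0, 0.0]))
        assert md[1] == pytest.approx(0.0, abs=1e-12)

    def test_identity_covariance_reduces_to_euclidean(self, rng):
        means = rng.normal(size=(3, 5))
        model = manual_model(means, np.eye(5))
        for _ in range(20):
            x = rng.normal(size=5)
            md = wm.mahalanobis_to_groups(model, x)
            np.testing.assert_allclose(
                md, np.linalg.norm(means - x, axis=1), atol=1e-10
            )

    def test_solver_matches_explicit_inverse(self, rng):
        for _ in range(10):
            a = rng.normal(size=(4, 4))
            spd = a @ a.T + 4 * np.eye(4)
            means = rng.normal(size=(3, 4))
            model = manual_model(means, spd)
            x = rng.normal(size=4)
            md = wm.mahalanobis_to_groups(model, x)
            inv = np.linalg.inv(spd)
            expected = np.sqrt(np.einsum("gi,ij,gj->g", means - x, inv, means - x))
            np.testing.assert_allclose(md, expected, atol=1e-8)

    def test_equidistant_point_splits_posterior(self):
        model = manual_model([[-2.0, 0.0], [2.0, 0.0]], np.eye(2))
        pp = wm.posterior_probabilities(model, np.array([0.0, 3.0]))
        np.testing.assert_allclose(pp, [0.5, 0.5], atol=1e-12)

    def test_posterior_concentrates_at_a_far_mean(self):
        model = manual_model([[0.0, 0.0], [10.0, 0.0]], np.eye(2))
        pp = wm.posterior_probabilities(model, np.array([10.0, 0.0]))
        assert pp[1] >= 0.99

    def test_nonfinite_input_rejected(self):
        model = manual_model([[0.0, 0.0], [1.0, 0.0]], np.eye(2))
        with pytest.raises(wm.ValidationError):
            wm.mahalanobis_to_groups(model, np.array([np.nan, 0.0]))

    def test_equal_priors_posterior_and_distance_agree(self, rng):
        means = rng.normal(size=(4, 6))
        a = rng.normal(size=(6, 6))
        model = manual_model(means, a @ a.T + 2 * np.eye(6))
        for _ in range(100):
            x = rng.normal(size=6)
            pp = wm.posterior_probabilities(model, x)
            md = wm.mahalanobis_to_groups(model, x)
            assert np.argmax(pp) == np.argmin(md)

    def test_exact_tie_breaks_lexicographically(self):
        model = manual_model([[-1.0, 0.0], [1.0, 0.0]], np.eye(2))
        with pytest.warns(RuntimeWarning, match="tie"):
            res = classify(model, np.array([0.0, 0.0]))
        assert res.assigned_group == "g1"


class TestLeaveOneOut:
    def test_separable_groups_recovered(self, separable_aligned):
        _, _, aligned, groups = separable_aligned
        report = wm.loo_crossvalidate(aligned.tangent, groups)
        assert report.global_hit_ratio >= 95.0
        assert report.confusion.values.sum() == len(groups)
        np.testing.assert_array_equal(
            report.confusion.sum(axis=1).values,
            [groups.count(g) for g in sorted(set(groups))],
        )
        assert report.global_hit_ratio == pytest.approx(
            100.0 * (report.n_total - report.n_misclassified) / report.n_total
        )

    def test_duplicated_specimens_classify_perfectly(self, separable_aligned):
        _, _, aligned, groups = separable_aligned
        x = np.vstack([aligned.tangent, aligned.tangent])
        report = wm.loo_crossvalidate(x, groups + groups)
        assert report.global_hit_ratio == 100.0

    def test_small_groups_rejected(self):
        x = np.random.default_rng(2).normal(size=(5, 3))
        with pytest.raises(wm.ValidationError, match="n >= 3"):
            wm.loo_crossvalidate(x, ["a", "a", "a", "b", "b"])

    def test_invariant_to_order_and_similarity_transform(self, rng, separable_dataset):
        spec, ds = separable_dataset
        aligned = wm.gpa(ds)
        groups = ds.labels.groups_at(aligned.specimen_ids, "group")
        base = wm.loo_crossvalidate(aligned.tangent, groups)
        perm = rng.permutation(ds.n)
        moved = [
            wm.LandmarkConfiguration(
                ds.configurations[i].specimen_id,
                random_similarity(rng, ds.configurations[i].coords),
            )
            for i in perm
        ]
        aligned2 = wm.gpa(moved)
        groups2 = ds.labels.groups_at(aligned2.specimen_ids, "group")
        report = wm.loo_crossvalidate(aligned2.tangent, groups2)
        assert report.global_hit_ratio == base.global_hit_ratio
        np.testing.assert_array_equal(report.confusion.values, base.confusion.values)

    def test_matches_sklearn_decisions(self, separable_aligned):
        # independent route: scikit-learn's LDA on a train/test split must
        # agree with our classifier (equal group sizes make the covariance
        # scaling convention irrelevant)
        sklearn_lda = pytest.importorskip("sklearn.discriminant_analysis")
        _, _, aligned, groups = separable_aligned
        x, y = aligned.tangent, np.asarray(groups)
        train = np.arange(len(y)) % 2 == 0
        model = wm.fit_lda(x[train], list(y[train]), priors_mode="proportional")
        ours = [classify(model, xi).assigned_group for xi in x[~train]]
        # same reduced basis for both, so the Gaussian scoring itself is
        # what gets cross-checked (equal group sizes make the covariance
        # pooling conventions coincide)
        ref = sklearn_lda.LinearDiscriminantAnalysis(solver="lsqr")
        ref.fit(model.reduce(x[train]), y[train])
        pred = ref.predict(model.reduce(x[~train]))
        np.testing.assert_array_equal(ours, pred)


class TestAssignment:
    def test_training_specimen_returns_home(self, separable_aligned):
        _, ds, aligned, groups = separable_aligned
        model = wm.fit_lda(aligned.tangent, groups)
        for idx in (0, ds.n // 2, ds.n - 1):
            unknown = wm.LandmarkConfiguration(
                "unknown", ds.configurations[idx].coords.copy()
            )
            res = wm.assign_unknown(model, unknown, aligned)
            assert res.assigned_group == groups[idx]
            assert sum(res.posterior.values()) == pytest.approx(1.0, abs=1e-12)

    def test_scheme_mismatch_rejected(self, separable_aligned):
        _, _, aligned, groups = separable_aligned
        model = wm.fit_lda(aligned.tangent, groups)
        bad = wm.LandmarkConfiguration("u", np.random.default_rng(0).normal(size=(5, 2)))
        with pytest.raises(wm.SchemeError, match="landmark"):
            wm.assign_unknown(model, bad, aligned)

    def test_replicate_unknowns_assigned_to_their_group(self, separable_aligned):
        spec, _, aligned, groups = separable_aligned
        model = wm.fit_lda(aligned.tangent, groups)
        names = sorted(set(groups))
        hits = 0
        for rep in range(40):
            g = names[rep % len(names)]
            unknown = wm.make_unknown(spec, g, seed=rep)
            if wm.assign_unknown(model, unknown, aligned).assigned_group == g:
                hits += 1
        assert hits >= 39

    def test_parameter_recovery_of_group_means(self, separable_aligned):
        # the fitted group means must sit within sampling error of the
        # tangent projections of the generating mean shapes
        spec, _, aligned, groups = separable_aligned
        model = wm.fit_lda(aligned.tangent, groups)
        gm = wm.make_group_means(spec)
        n = spec.n_per_group
        for gi, g in enumerate(model.groups):
            _, t = wm.align_to_consensus(
                wm.LandmarkConfiguration(g, gm.means[g]), aligned.consensus
            )
            fitted = model.group_means[gi] @ model.components + model.grand_mean
            err = fitted - t
            rms = np.sqrt(np.mean(err**2))
            assert rms < 2.0 * spec.within_sd / np.sqrt(n), rms
            assert np.abs(err).max() < 5.0 * spec.within_sd / np.sqrt(n)


@pytest.fixture(scope="module")
def nested():
    spec = wm.SyntheticSpec(
        hierarchy=(("tribe", 3), ("subgenus", 2)),
        n_per_group=6,
        within_sd=0.01,
        separation=10.0,
        seed=13,
    )
    return spec, wm.generate_dataset(spec)


class TestHierarchicalAssign:
    def test_single_stage_equals_assign_unknown(self, nested):
        spec, ds = nested
        unknown = wm.make_unknown(spec, "subgenus1", seed=1)
        chain = wm.hierarchical_assign(unknown, [(ds, "tribe")])
        aligned = wm.gpa(ds)
        model = wm.fit_lda(
            aligned.tangent,
            ds.labels.groups_at(aligned.specimen_ids, "tribe"),
            grouping_level="tribe",
        )
        direct = wm.assign_unknown(model, unknown, aligned)
        assert len(chain) == 1
        assert chain[0].assigned_group == direct.assigned_group
        assert chain[0].posterior == pytest.approx(direct.posterior, abs=1e-12)

    def test_chain_ends_at_true_subgenus(self, nested):
        spec, ds = nested
        unknown = wm.make_unknown(spec, "subgenus5", seed=2)
        tribe = wm.make_group_means(spec).labels["subgenus5"]["tribe"]
        within = ds.subset(
            sid for sid in ds.specimen_ids
            if ds.labels.group_of(sid, "tribe") == tribe
        )
        chain = wm.hierarchical_assign(unknown, [(ds, "tribe"), (within, "subgenus")])
        assert chain[0].assigned_group == tribe
        assert chain[1].assigned_group == "subgenus5"

    def test_specimen_order_does_not_matter(self, nested, rng):
        spec, ds = nested
        unknown = wm.make_unknown(spec, "subgenus3", seed=3)
        shuffled = wm.ShapeDataset(
            [ds.configurations[i] for i in rng.permutation(ds.n)], ds.labels
        )
        c1 = wm.hierarchical_assign(unknown, [(ds, "tribe"), (ds, "subgenus")])
        c2 = wm.hierarchical_assign(unknown, [(shuffled, "tribe"), (shuffled, "subgenus")])
        for r1, r2 in zip(c1, c2):
            assert r1.assigned_group == r2.assigned_group
            for g in r1.groups:
                assert r1.posterior[g] == pytest.approx(r2.posterior[g], abs=1e-8)

    def test_stage_failure_reports_index(self, nested):
        spec, ds = nested
        unknown = wm.make_unknown(spec, "subgenus1", seed=4)
        with pytest.raises(wm.ValidationError, match="stage 1"):
            wm.hierarchical_assign(unknown, [(ds, "tribe"), (ds, "species")])
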