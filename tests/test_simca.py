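"""SIMCA class modeling: PCA subspaces, distances, diagnostics, metrics."""

import numpy as np
import pandas as pd
import pytest

import honeyspec as hs
from honeyspec.errors import (
    ConfigError,
    DegenerateClassError,
    LabelError,
    RankError,
)
from honeyspec.simca import _loo_residual_variance


def _class_data(n=30, J=12, rank=2, noise=0.01, seed=0):
    rng = np.random.default_rng(seed)
    T = rng.normal(size=(n, rank)) * np.array([3.0, 1.0][:rank])
    V = np.linalg.qr(rng.normal(size=(J, rank)))[0]
    return 5.0 + T @ V.T + noise * rng.normal(size=(n, J))


class TestFitClassModel:
    def test_loadings_orthonormal(self):
        X = _class_data()
        m = hs.fit_class_model(X, 2)
        np.testing.assert_allclose(
            m.pc_loadings @ m.pc_loadings.T, np.eye(2), atol=1e-10
        )

    def test_variance_conservation(self):
        X = _class_data(noise=0.1)
        m = hs.fit_class_model(X, 2)
        Xc = X - X.mean(0)
        total = (Xc**2).sum()
        captured = m.explained_variance.sum() * total
        resid = ((Xc - (Xc @ m.pc_loadings.T) @ m.pc_loadings) ** 2).sum()
        assert captured + resid == pytest.approx(total, abs=1e-10 * total)

    def test_exact_subspace_hits_variance_floor(self):
        X = _class_data(noise=0.0, rank=1)
        m = hs.fit_class_model(X, 1)
        assert m.s0_sq == pytest.approx(1e-12)  # epsilon floor, degenerate

    def test_explained_variance_in_unit_interval(self):
        m = hs.fit_class_model(_class_data(noise=0.5), 3)
        assert ((m.explained_variance >= 0) & (m.explained_variance <= 1)).all()

    def test_four_pcs_explain_study_training_variance(self, default_cohort):
        # the authentication regime: 4 factors explain >= 99% of the
        # training spectra variance in the sugar fingerprint window
        sub = hs.select_region(default_cohort.dataset, hs.DEFAULT_SIMCA_REGION)
        labels = sub.class_labels.to_numpy()
        for cls in ("pure", "suspicious"):
            m = hs.fit_class_model(sub.matrix[labels == cls], 4)
            assert m.explained_variance.sum() >= 0.99

    def test_explained_variance_matches_reference_pca(self):
        PCA = pytest.importorskip("sklearn.decomposition").PCA
        X = _class_data(n=25, J=10, noise=0.3)
        m = hs.fit_class_model(X, 3)
        ref = PCA(n_components=3).fit(X)
        total = ((X - X.mean(0)) ** 2).sum()
        np.testing.assert_allclose(
            m.explained_variance, ref.explained_variance_ * (25 - 1) / total,
            atol=1e-10,
        )

    def test_too_many_pcs_rejected(self):
        with pytest.raises(RankError):
            hs.fit_class_model(_class_data(n=5), 4)

    def test_bad_alpha_rejected(self):
        with pytest.raises(ConfigError):
            hs.fit_class_model(_class_data(), 2, alpha=1.5)


class TestSampleDistance:
    def test_mean_spectrum_is_at_distance_zero(self):
        m = hs.fit_class_model(_class_data(), 2)
        assert hs.sample_distance(m, m.mean_spectrum) == pytest.approx(0.0)

    def test_in_subspace_points_at_distance_zero(self):
        m = hs.fit_class_model(_class_data(), 2)
        x = m.mean_spectrum + 3.0 * m.pc_loadings[0] - 1.5 * m.pc_loadings[1]
        assert hs.sample_distance(m, x) == pytest.approx(0.0, abs=1e-6)

    def test_matches_hand_computed_oracle(self):
        # 3-point grid, 4 samples on a known 1-PC line plus noise; the
        # oracle recomputes mean, loading, LOO-pooled s0 and the residual
        # distance with explicit loops.
        X = np.array(
            [
                [1.0, 0.0, 0.2],
                [2.0, 0.1, -0.1],
                [3.0, -0.1, 0.05],
                [4.0, 0.05, -0.15],
            ]
        )
        m = hs.fit_class_model(X, 1)
        x = np.array([2.5, 0.3, 0.4])

        def residual(train, point, npc=1):
            mu = train.mean(axis=0)
            _, _, Vt = np.linalg.svd(train - mu, full_matrices=False)
            P = Vt[:npc]
            e = (point - mu) - P.T @ (P @ (point - mu))
            return float(e @ e)

        s0 = np.mean(
            [
                residual(np.delete(X, i, axis=0), X[i]) / (3 - 1)
                for i in range(4)
            ]
        )
        expected = np.sqrt((residual(X, x) / (3 - 1)) / s0)
        assert hs.sample_distance(m, x) == pytest.approx(expected, abs=1e-12)

    def test_loo_pooled_variance_against_direct_loop(self):
        X = _class_data(n=10, J=6, noise=0.2, seed=4)
        direct = []
        for i in range(10):
            Xi = np.delete(X, i, axis=0)
            mu = Xi.mean(0)
            _, _, Vt = np.linalg.svd(Xi - mu, full_matrices=False)
            P = Vt[:2]
            e = (X[i] - mu) - P.T @ (P @ (X[i] - mu))
            direct.append(e @ e / (6 - 2))
        assert _loo_residual_variance(X, 2) == pytest.approx(
            np.mean(direct), abs=1e-14
        )


class TestClassify:
    @staticmethod
    def _two_class_model(seed=0):
        rng = np.random.default_rng(seed)
        V = np.linalg.qr(rng.normal(size=(10, 2)))[0]
        X1 = rng.normal(size=(20, 1)) * 2 @ V[:, :1].T + 0.01 * rng.normal(
            size=(20, 10)
        )
        X2 = 10.0 + rng.normal(size=(20, 1)) * 2 @ V[:, 1:].T
        X2 = X2 + 0.01 * rng.normal(size=(20, 10))
        X = np.vstack([X1, X2])
        labels = ["a"] * 20 + ["b"] * 20
        return hs.fit_simca(X, labels, n_pc=1), X1, X2

    def test_deep_inside_one_class(self):
        model, X1, _ = self._two_class_model()
        result = hs.classify(model, X1[0])
        assert result.assigned[0] == {"a"}

    def test_far_from_both_classes_assigned_none(self):
        model, X1, _ = self._two_class_model()
        result = hs.classify(model, X1[0] + 100.0)
        assert result.assigned[0] == set()

    def test_identical_classes_agree(self):
        rng = np.random.default_rng(1)
        X = _class_data(n=24, J=8, noise=0.05, seed=2)
        labels = ["a"] * 12 + ["b"] * 12
        # same data in both classes
        model = hs.fit_simca(np.vstack([X[:12], X[:12]]), labels, n_pc=1)
        for x in np.vstack([X[12:], X[:3] + 50]):
            assigned = hs.classify(model, x).assigned[0]
            assert assigned in (set(), {"a", "b"})

    def test_empty_model_rejected(self):
        model, _, _ = self._two_class_model()
        model.class_models = []
        with pytest.raises(ConfigError):
            hs.classify(model, np.zeros(10))

    def test_acceptance_region_calibrated(self):
        # samples from the class's own generative model are accepted at
        # well above the nominal 95% rate (the limit is conservative)
        cfg = hs.CohortConfig(n_samples=60, n_adulterated=0, seed=301)
        train = hs.generate_cohort(cfg)
        region = hs.DEFAULT_SIMCA_REGION
        sub = hs.select_region(train.dataset, region)
        m = hs.fit_class_model(sub.matrix, 4, class_label="pure")
        fresh = hs.generate_cohort(
            hs.CohortConfig(n_samples=1000, n_adulterated=0, seed=302)
        )
        Xf = hs.select_region(fresh.dataset, region).matrix
        d2 = np.array([hs.sample_distance(m, x) ** 2 for x in Xf])
        assert (d2 > m.f_crit).mean() <= 0.10


class TestInterclassDistance:
    def test_identical_classes_at_zero(self):
        X = _class_data(noise=0.1)
        m = hs.fit_class_model(X, 2)
        assert hs.interclass_distance(m, m, X, X) == pytest.approx(0.0)

    def test_symmetric(self):
        X1 = _class_data(seed=1, noise=0.1)
        X2 = _class_data(seed=2, noise=0.1) + 1.0
        m1 = hs.fit_class_model(X1, 2)
        m2 = hs.fit_class_model(X2, 2)
        assert hs.interclass_distance(m1, m2, X1, X2) == hs.interclass_distance(
            m2, m1, X2, X1
        )

    def test_non_negative(self):
        X1 = _class_data(seed=3, noise=0.1)
        X2 = _class_data(seed=4, noise=0.1)
        m1, m2 = hs.fit_class_model(X1, 2), hs.fit_class_model(X2, 2)
        assert hs.interclass_distance(m1, m2, X1, X2) >= 0.0

    def test_degenerate_classes_rejected(self):
        X = _class_data(noise=0.0, rank=1)
        m = hs.fit_class_model(X, 1)
        with pytest.raises(DegenerateClassError):
            hs.interclass_distance(m, m, X, X)

    def test_study_cohort_classes_well_separated(self, study_report):
        assert study_report.simca_summary["interclass_distance"] > 3.0


class TestDiscriminatingPower:
    def test_identical_classes_exactly_one(self):
        # same data in both classes -> identical models -> cross residuals
        # equal self residuals -> DP = 1 at every wavenumber
        X = _class_data(n=20, noise=0.2)
        m1 = hs.fit_class_model(X, 2)
        m2 = hs.fit_class_model(X.copy(), 2)
        dp = hs.discriminating_power(m1, m2, X, X.copy())
        np.testing.assert_allclose(dp, 1.0, atol=1e-10)

    def test_same_population_classes_near_one(self):
        X = _class_data(n=60, noise=0.05)
        m1 = hs.fit_class_model(X[:30], 2)
        m2 = hs.fit_class_model(X[30:], 2)
        dp = hs.discriminating_power(m1, m2, X[:30], X[30:])
        assert np.median(np.abs(dp - 1.0)) < 0.5

    def test_swap_invariant(self):
        X1 = _class_data(seed=5, noise=0.1)
        X2 = _class_data(seed=6, noise=0.1) + 0.5
        m1, m2 = hs.fit_class_model(X1, 2), hs.fit_class_model(X2, 2)
        np.testing.assert_allclose(
            hs.discriminating_power(m1, m2, X1, X2),
            hs.discriminating_power(m2, m1, X2, X1),
            atol=1e-12,
        )

    def test_peaks_at_adulterant_band(self, study_report):
        dp = study_report.discriminating_power
        peak = dp.index[np.argmax(dp.iloc[:, 0].to_numpy())]
        assert 990.0 <= peak <= 1030.0


class TestModelingPower:
    def test_full_rank_model_near_one(self):
        X = _class_data(noise=1e-6, rank=2)
        m = hs.fit_class_model(X, 2)
        mp = hs.modeling_power(m, X)
        assert np.nanmin(mp) > 0.99

    def test_mean_only_model_is_zero(self):
        X = _class_data(noise=0.3)
        m = hs.fit_class_model(X, 0)
        np.testing.assert_allclose(hs.modeling_power(m, X), 0.0, atol=1e-12)

    def test_matches_manual_two_variable_oracle(self):
        X = np.array([[0.0, 1.0], [1.0, 3.0], [2.0, 5.0], [3.0, 6.0], [4.0, 9.0]])
        m = hs.fit_class_model(X, 1)
        n = 5
        Xc = X - X.mean(0)
        P = m.pc_loadings
        E = Xc - (Xc @ P.T) @ P
        expected = 1.0 - np.sqrt(
            (E**2).sum(0) / (n - 1 - 1)
        ) / np.sqrt((Xc**2).sum(0) / (n - 1))
        np.testing.assert_allclose(
            hs.modeling_power(m, X), np.clip(expected, 0, 1), atol=1e-12
        )

    def test_zero_variance_column_not_applicable(self):
        X = _class_data(n=10, J=4, noise=0.1, seed=7)
        X[:, 2] = 3.0
        m = hs.fit_class_model(X, 1)
        mp = hs.modeling_power(m, X)
        assert np.isnan(mp[2])


class TestPerformance:
    @staticmethod
    def _result(assigned, classes=("pure", "suspicious")):
        n = len(assigned)
        distances = pd.DataFrame(
            np.ones((n, len(classes))), columns=list(classes)
        )
        return hs.ClassificationResult(distances=distances, assigned=assigned)

    def test_perfect_exclusive_assignment(self):
        truth = ["pure"] * 25 + ["suspicious"] * 4
        assigned = [{"pure"}] * 25 + [{"suspicious"}] * 4
        stats = hs.performance(self._result(assigned), truth, "suspicious")
        assert (
            stats.sensitivity, stats.specificity, stats.accuracy, stats.precision
        ) == (1.0, 1.0, 1.0, 1.0)
        assert stats.misclassified == 0

    def test_hand_computed_confusion(self):
        truth = ["suspicious"] * 5 + ["pure"] * 24
        assigned = (
            [{"suspicious"}] * 4 + [set()] + [{"pure"}] * 24
        )  # tp=4 fn=1 tn=24 fp=0
        stats = hs.performance(self._result(assigned), truth, "suspicious")
        assert stats.sensitivity == pytest.approx(0.8)
        assert stats.specificity == 1.0
        assert stats.precision == 1.0
        assert stats.accuracy == pytest.approx(28 / 29)

    def test_multi_assignment_of_positive_counts_as_miss(self):
        truth = ["suspicious", "pure"]
        assigned = [{"suspicious", "pure"}, {"pure", "suspicious"}]
        stats = hs.performance(self._result(assigned), truth, "suspicious")
        assert stats.fn == 1 and stats.fp == 1

    def test_no_positives_reports_not_applicable(self):
        truth = ["pure"] * 3
        stats = hs.performance(
            self._result([{"pure"}] * 3), truth, "suspicious"
        )
        assert stats.sensitivity is None
        assert stats.specificity == 1.0

    def test_unknown_truth_label_rejected(self):
        with pytest.raises(LabelError):
            hs.performance(self._result([{"pure"}]), ["mystery"], "suspicious")


class TestCrossValidatedMisclassification:
    def test_well_separated_blobs_have_none(self):
        rng = np.random.default_rng(9)
        X1 = rng.normal(size=(15, 8)) * 0.1
        X2 = rng.normal(size=(15, 8)) * 0.1 + 5.0
        labels = ["a"] * 15 + ["b"] * 15
        assert hs.cross_validated_misclassifications(
            np.vstack([X1, X2]), labels, n_pc=2
        ) == 0

    def test_single_class_rejected(self):
        with pytest.raises(ConfigError):
            hs.cross_validated_misclassifications(
                _class_data(), ["a"] * 30, n_pc=2
            )


class TestSelectNPc:
    def test_recovers_subspace_dimension(self):
        X = _class_data(n=40, J=10, rank=2, noise=0.01, seed=12)
        assert hs.select_n_pc(X, max_pc=6) == 2


class TestSerialization:
    def test_simca_model_json_round_trip(self, tmp_path):
        import json

        model, X1, _ = TestClassify._two_class_model()
        path = tmp_path / "simca.json"
        path.write_text(json.dumps(model.to_dict()))
        back = hs.SIMCAModel.from_dict(json.loads(path.read_text()))
        orig = hs.classify(model, X1[:5])
        re = hs.classify(back, X1[:5])
        assert orig.assigned == re.assigned
        np.testing.assert_allclose(
            orig.distances.to_numpy(), re.distances.to_numpy(), atol=1e-12
        )
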