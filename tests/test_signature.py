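import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from mirmod import (
    ExpressionMatrix,
    SampleMetadata,
    Signature,
    classifier_accuracy,
    cluster_samples,
    differential_expression,
    pca_view,
    random_signature_null,
    survival_analysis,
)


def _em(values, prefix="miR"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        [f"{prefix}-{i:03d}" for i in range(values.shape[0])],
        [f"S{j:03d}" for j in range(values.shape[1])],
        values,
    )


def _two_class_data(rng, n_feat=30, n_sig=5, n0=40, n1=60, shift=5.0):
    """Background noise everywhere; signature rows mean-shifted in class 1."""
    X = rng.standard_normal((n_feat, n0 + n1))
    X[:n_sig, n0:] += shift
    em = _em(X)
    y = np.array(["ctrl"] * n0 + ["case"] * n1)
    sig = Signature(em.feature_ids[:n_sig])
    return em, y, sig


class TestClassifierAccuracy:
    def test_separated_classes_classified(self, rng):
        em, y, sig = _two_class_data(rng)
        assert classifier_accuracy(em, y, sig, seed=0) >= 0.95

    def test_permuted_labels_fall_to_majority_rate(self, rng):
        em, y, sig = _two_class_data(rng)
        y_perm = rng.permutation(y)
        acc = classifier_accuracy(em, y_perm, sig, seed=0)
        assert abs(acc - 0.6) < 0.15  # majority class is 60/100

    def test_uninformative_signature_near_chance(self, rng):
        em, y, _ = _two_class_data(rng)
        noise_sig = Signature(em.feature_ids[-5:])
        acc = classifier_accuracy(em, y, noise_sig, seed=0)
        assert abs(acc - 0.6) < 0.15

    def test_invariant_to_feature_order(self, rng):
        em, y, sig = _two_class_data(rng)
        reordered = Signature(list(reversed(sig.mirna_ids)))
        assert classifier_accuracy(em, y, sig, seed=0) == classifier_accuracy(
            em, y, reordered, seed=0
        )

    def test_single_class_rejected(self, rng):
        em, _, sig = _two_class_data(rng)
        with pytest.raises(ValueError, match="2 classes"):
            classifier_accuracy(em, ["case"] * em.n_samples, sig)


class TestRandomSignatureNull:
    def test_planted_signal_reaches_pseudocount_floor(self, rng):
        # moderate per-feature shift: the full signature separates well but a
        # random list catching one signal row cannot match it
        em, y, sig = _two_class_data(rng, n_feat=120, n0=50, n1=50, shift=1.2)
        res = random_signature_null(em, y, k=5, n_lists=60, seed=0, sig=sig)
        assert res.empirical_p == pytest.approx(1 / 61)
        assert res.signature_accuracy > res.null_mean_accuracy

    def test_signal_everywhere_makes_signature_unremarkable(self, rng):
        X = rng.standard_normal((40, 100))
        X[:, 50:] += 3.0  # every row carries the same strong signal
        em = _em(X)
        y = np.array(["a"] * 50 + ["b"] * 50)
        res = random_signature_null(
            em, y, k=5, n_lists=40, seed=0, sig=Signature(em.feature_ids[:5])
        )
        assert res.empirical_p > 0.5

    def test_single_null_list_beating_signature_gives_p_one(self, rng):
        X = rng.standard_normal((40, 60))
        X[5:10, 30:] += 5.0  # signal on NON-signature rows only
        em = _em(X)
        y = np.array(["a"] * 30 + ["b"] * 30)
        res = random_signature_null(
            em, y, k=5, n_lists=1, seed=1, sig=Signature(em.feature_ids[:5])
        )
        if res.null_accuracies[0] >= res.signature_accuracy:
            assert res.empirical_p == 1.0

    def test_requires_enough_nonsignature_rows(self, rng):
        em, y, sig = _two_class_data(rng, n_feat=8)
        with pytest.raises(ValueError, match="non-signature"):
            random_signature_null(em, y, k=5, n_lists=5, seed=0, sig=sig)


class TestPcaView:
    def test_rank_one_matrix_explained_by_first_component(self, rng):
        u = rng.standard_normal(6)[:, None]
        v = rng.standard_normal(50)[None, :]
        em = _em(u @ v + 1e-9 * rng.standard_normal((6, 50)))
        coords, evr = pca_view(em, Signature(em.feature_ids))
        assert evr[0] > 0.999
        assert coords.shape == (50, 3)

    def test_separated_classes_separate_on_pc1(self, rng):
        X = rng.standard_normal((5, 80))
        X[:, 40:] += 4.0
        em = _em(X)
        coords, _ = pca_view(em, Signature(em.feature_ids))
        gap = abs(coords[40:, 0].mean() - coords[:40, 0].mean())
        within = max(coords[:40, 0].std(), coords[40:, 0].std())
        assert gap > 3 * within

    def test_duplicated_samples_identical_coordinates(self, rng):
        X = rng.standard_normal((5, 20))
        X[:, 10:] = X[:, :10]
        em = _em(X)
        coords, _ = pca_view(em, Signature(em.feature_ids))
        np.testing.assert_allclose(coords[:10], coords[10:], atol=1e-10)

    def test_sign_convention_deterministic(self, rng):
        X = rng.standard_normal((5, 30))
        em = _em(X)
        c1, _ = pca_view(em, Signature(em.feature_ids))
        c2, _ = pca_view(em, Signature(em.feature_ids))
        np.testing.assert_array_equal(c1, c2)

    def test_too_few_features_rejected(self, rng):
        em = _em(rng.standard_normal((2, 30)))
        with pytest.raises(ValueError, match="3 signature"):
            pca_view(em, Signature(em.feature_ids))


class TestClusterSamples:
    @pytest.mark.parametrize("method", ["kmeans", "hierarchical"])
    def test_two_blobs_recovered(self, rng, method):
        X = rng.standard_normal((4, 60))
        X[:, 30:] += 6.0
        em = _em(X)
        labels = cluster_samples(em, Signature(em.feature_ids), method=method)
        truth = np.array([0] * 30 + [1] * 30)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_three_groups_recovered(self, rng):
        X = rng.standard_normal((4, 90))
        X[:, 30:60] += 6.0
        X[:, 60:] -= 6.0
        em = _em(X)
        labels = cluster_samples(em, Signature(em.feature_ids), n_groups=3, seed=0)
        truth = np.array([0] * 30 + [1] * 30 + [2] * 30)
        assert adjusted_rand_score(truth, labels) >= 0.9

    def test_deterministic_under_seed(self, rng):
        X = rng.standard_normal((4, 50))
        em = _em(X)
        l1 = cluster_samples(em, Signature(em.feature_ids), seed=3)
        l2 = cluster_samples(em, Signature(em.feature_ids), seed=3)
        np.testing.assert_array_equal(l1, l2)

    def test_more_groups_than_samples_rejected(self, rng):
        em = _em(rng.standard_normal((4, 10)))
        with pytest.raises(ValueError, match="exceed"):
            cluster_samples(em, Signature(em.feature_ids), n_groups=11)


def _survival_fixture(rng, hr=4.0, n=120, risk_gap=3.0):
    """Two latent risk clusters in signature space with exponential survival."""
    X = rng.standard_normal((6, n))
    high_risk = np.zeros(n, dtype=bool)
    high_risk[: n // 2] = True
    X[:, high_risk] -= risk_gap  # low expression = aggressive
    em = _em(X)
    hazard = 0.03 * np.where(high_risk, hr, 1.0)
    t_event = rng.exponential(1 / hazard)
    censor = rng.uniform(0, 40, n)
    meta = SampleMetadata(
        em.sample_ids,
        ["primary"] * n,
        np.minimum(t_event, censor),
        t_event <= censor,
    )
    return em, meta, high_risk


class TestSurvivalAnalysis:
    def test_risk_groups_and_hazard_recovered(self, rng):
        em, meta, truth = _survival_fixture(rng)
        res = survival_analysis(em, Signature(em.feature_ids), meta, seed=0)
        np.testing.assert_array_equal(res.groups.astype(bool), truth)
        assert res.hr_ci[0] <= 4.0 <= res.hr_ci[1]
        assert res.logrank_p < 0.01
        assert set(res.km_curves) == {0, 1}

    def test_univariate_and_multivariate_tables_complete(self, rng):
        em, meta, _ = _survival_fixture(rng)
        res = survival_analysis(em, Signature(em.feature_ids), meta, seed=0)
        assert len(res.univariate) == 6
        assert len(res.multivariate) == 6
        # low expression is the aggressive direction: negative coefficients
        assert (res.univariate["coef"] < 0).all()

    def test_no_events_rejected(self, rng):
        em, meta, _ = _survival_fixture(rng)
        meta_none = SampleMetadata(
            meta.sample_ids, meta.class_label,
            meta.time_to_event, np.zeros(len(meta.sample_ids), dtype=bool),
        )
        with pytest.raises(ValueError, match="events"):
            survival_analysis(em, Signature(em.feature_ids), meta_none, seed=0)

    def test_all_zero_followup_in_group_rejected(self, rng):
        em, meta, truth = _survival_fixture(rng)
        time = meta.time_to_event.copy()
        time[truth] = 0.0
        meta_degenerate = SampleMetadata(
            meta.sample_ids, meta.class_label, time, meta.event_flag
        )
        with pytest.raises(ValueError, match="degenerate"):
            survival_analysis(em, Signature(em.feature_ids), meta_degenerate, seed=0)


class TestDifferentialExpression:
    def test_identical_means_give_unit_fold_change(self, rng):
        half = rng.standard_normal((8, 30)) + 5.0
        em = _em(np.hstack([half, half]))
        y = np.array(["ctrl"] * 30 + ["case"] * 30)
        de = differential_expression(em, y, case="case", control="ctrl",
                                     n_perm=200, seed=0)
        np.testing.assert_allclose(de.fold_change, 1.0, atol=1e-12)
        assert (de.p > 0.9).all()  # duplicated halves: no permutation beats zero... all do

    def test_exact_halving_detected(self, rng):
        base = rng.uniform(2.0, 4.0, size=(5, 1))
        ctrl = np.tile(base, (1, 10))
        case = 0.5 * ctrl
        em = _em(np.hstack([ctrl, case]))
        y = np.array(["ctrl"] * 10 + ["case"] * 10)
        de = differential_expression(em, y, case="case", control="ctrl",
                                     n_perm=100, seed=0)
        np.testing.assert_allclose(de.fold_change, 0.5, atol=1e-12)

    def test_log_scale_twofold_down_recovered_at_fdr(self, rng):
        X = rng.standard_normal((40, 60)) * 0.3
        X[:5, 30:] -= 1.0  # 2-fold down on log2 scale
        em = _em(X)
        y = np.array(["ctrl"] * 30 + ["case"] * 30)
        de = differential_expression(em, y, case="case", control="ctrl",
                                     log_scale=True, n_perm=400, seed=0)
        hits = set(de[de.q < 0.1].feature)
        assert set(em.feature_ids[:5]) <= hits
        planted = de.set_index("feature").loc[em.feature_ids[:5], "fold_change"]
        assert np.allclose(planted, 0.5, atol=0.15)

    def test_nonpositive_means_demand_log_flag(self, rng):
        em = _em(rng.standard_normal((4, 20)))
        y = np.array(["ctrl"] * 10 + ["case"] * 10)
        with pytest.raises(ValueError, match="log_scale"):
            differential_expression(em, y, case="case", control="ctrl")

    def test_tiny_classes_rejected(self, rng):
        em = _em(rng.standard_normal((4, 5)) + 10)
        y = np.array(["ctrl"] * 2 + ["case"] * 3)
        with pytest.raises(ValueError, match="3 samples"):
            differential_expression(em, y, case="case", control="ctrl")
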