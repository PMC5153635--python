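import numpy as np
import pytest

from docnet import mvpa


def _toy_features(rng, n_per_class, sep=4.0, n_feat=6, classes=("A", "B", "C")):
    """Gaussian blobs, one per class, separated by `sep` SDs."""
    X, y = [], []
    for k, cls in enumerate(classes):
        centre = np.zeros(n_feat)
        centre[k % n_feat] = sep
        X.append(centre + rng.standard_normal((n_per_class, n_feat)))
        y += [cls] * n_per_class
    return np.vstack(X), np.asarray(y, dtype=object)


class TestBuildFeatures:
    @staticmethod
    def _fake_profiles(parc, n_subjects, rng):
        from docnet.topology import TopologyProfile

        profs = []
        for s in range(n_subjects):
            auc = {m: rng.random(parc.n_nodes) for m in mvpa.FEATURE_METRICS}
            profs.append(TopologyProfile(
                subject_id=f"s{s}", group="MCS",
                densities=np.array([0.1, 0.2]),
                raw={}, normalized={}, nodal_auc=auc))
        return profs

    def test_study_sized_feature_count(self, default_parc, rng):
        profs = self._fake_profiles(default_parc, 3, rng)
        fm = mvpa.build_features(profs, default_parc, ["FPN", "DMN"])
        assert fm.X.shape == (3, 3 * (25 + 58))
        assert len(fm.feature_index) == 249

    def test_deterministic_column_order(self, small_parc, rng):
        profs = self._fake_profiles(small_parc, 2, rng)
        a = mvpa.build_features(profs, small_parc, ["FPN"])
        b = mvpa.build_features(profs, small_parc, ["FPN"])
        assert a.feature_index == b.feature_index
        assert np.array_equal(a.X, b.X)
        metrics = [m for _, _, m in a.feature_index[:3]]
        assert metrics == ["strength", "betweenness", "degree"]

    def test_values_match_profile_entries(self, small_parc, rng):
        profs = self._fake_profiles(small_parc, 1, rng)
        fm = mvpa.build_features(profs, small_parc, ["DMN"])
        for col, (net, node, metric) in enumerate(fm.feature_index):
            assert fm.X[0, col] == profs[0].nodal_auc[metric][node]


class TestTrainAndDecode:
    def test_separable_training_is_perfect(self, rng):
        X, y = _toy_features(rng, 8, sep=6.0)
        model = mvpa.train_ovr(X, y)
        scores = model.decision_scores(X)
        preds = [model.classes[mvpa.decode(s)] for s in scores]
        assert preds == y.tolist()

    def test_weight_vector_dimension(self, rng):
        X, y = _toy_features(rng, 5, n_feat=11)
        model = mvpa.train_ovr(X, y)
        assert model.coefs().shape == (3, 11)

    def test_duplicated_feature_column_regularized(self, rng):
        X, y = _toy_features(rng, 5)
        X = np.hstack([X, X[:, :1]])
        model = mvpa.train_ovr(X, y)
        assert np.all(np.isfinite(model.coefs()))

    def test_missing_class_rejected(self, rng):
        X, y = _toy_features(rng, 4, classes=("A", "B"))
        with pytest.raises(ValueError):
            mvpa.train_ovr(X, y, classes=["A", "B", "C"])

    def test_decode_argmax_and_ties(self, rng):
        assert mvpa.decode([2.0, -1.0, -1.0]) == 0
        assert mvpa.decode([0.5, 0.5, -1.0]) == 0
        for _ in range(50):
            s = rng.standard_normal(3)
            assert mvpa.decode(s) == int(np.argmax(s))
        with pytest.raises(ValueError):
            mvpa.decode([np.nan, 0.0, 1.0])


class TestLoocv:
    def test_separable_cohort_is_perfect(self, rng):
        X, y = _toy_features(rng, 7, sep=8.0)
        rep = mvpa.loocv(X, y)
        assert rep.accuracy_pct == 100.0

    def test_accounting_identity(self, rng):
        X, y = _toy_features(rng, 5, sep=1.0)
        rep = mvpa.loocv(X, y)
        total_correct = sum(c for c, _ in rep.per_class.values())
        assert rep.accuracy_pct == pytest.approx(
            100.0 * total_correct / rep.n_subjects)

    def test_binary_sensitivity_specificity_identity(self, rng):
        X, y = _toy_features(rng, 6, sep=2.0, classes=("VS_UWS", "CONTROL"))
        rep = mvpa.loocv(X, y)
        assert rep.positive_class == "VS_UWS"
        assert rep.accuracy_pct == pytest.approx(mvpa.binary_accuracy(
            rep.sensitivity_pct, rep.specificity_pct, 6, 6))

    def test_invariant_to_subject_order(self, rng):
        X, y = _toy_features(rng, 5, sep=1.5)
        rep = mvpa.loocv(X, y)
        perm = rng.permutation(len(y))
        rep2 = mvpa.loocv(X[perm], y[perm])
        pred_map = dict(zip(perm.tolist(), rep2.predictions))
        assert [pred_map[i] for i in range(len(y))] == rep.predictions

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(5)
        X, y = _toy_features(rng, 6, sep=5.0)
        accs = []
        for _ in range(50):
            ys = y[rng.permutation(y.size)]
            accs.append(mvpa.loocv(X, ys).accuracy_pct)
        mean = np.mean(accs)
        se = np.std(accs) / np.sqrt(len(accs))
        assert abs(mean - 100.0 / 3) <= 3 * se + 3.0


class TestPermutationPvalue:
    def test_counting_oracle(self, rng):
        null = np.concatenate([np.full(49, 80.0), np.full(951, 20.0)])
        assert mvpa.pvalue_from_null(null, 75.0) == pytest.approx(0.049)

    def test_actual_below_all_nulls(self):
        assert mvpa.pvalue_from_null(np.full(100, 90.0), 10.0) == 1.0

    def test_separable_cohort_significant(self, rng):
        X, y = _toy_features(rng, 6, sep=8.0)
        p, acc, null = mvpa.permutation_pvalue(X, y, n_perm=49, seed=3)
        assert acc == 100.0
        assert p < 0.05


class TestNodalWeightMap:
    def test_zero_weights_zero_map(self):
        model = mvpa.OvrModel(classes=["A"], models=[], mean=0, scale=1)
        model.coefs = lambda: np.zeros((3, 6))
        idx = [("N", n, m) for n in (0, 1) for m in mvpa.FEATURE_METRICS]
        out = mvpa.nodal_weight_map(model, idx)
        assert all(v == 0.0 for v in out.values())

    def test_both_conventions_on_known_weights(self):
        model = mvpa.OvrModel(classes=["A"], models=[], mean=0, scale=1)
        model.coefs = lambda: np.array([[1.0, -2.0, 0.5]])
        idx = [("N", 0, m) for m in mvpa.FEATURE_METRICS]
        assert mvpa.nodal_weight_map(model, idx)[0] == pytest.approx(0.5)
        assert mvpa.nodal_weight_map(model, idx, mode="abs-then-sum")[0] == \
            pytest.approx(3.5)

    def test_matches_direct_summation_oracle(self, rng):
        coefs = rng.standard_normal((3, 9))
        model = mvpa.OvrModel(classes=["A", "B", "C"], models=[], mean=0, scale=1)
        model.coefs = lambda: coefs
        idx = [("N", n, m) for n in range(3) for m in mvpa.FEATURE_METRICS]
        out = mvpa.nodal_weight_map(model, idx)
        for n in range(3):
            cols = slice(3 * n, 3 * n + 3)
            assert out[n] == pytest.approx(abs(coefs[:, cols].sum()))


class TestAccuracyBookkeeping:
    def test_counts_to_accuracy(self):
        assert mvpa.accuracy_from_counts([9, 4, 6], [11, 7, 11]) == \
            pytest.approx(100 * 19 / 29)

    def test_binary_identity_exact(self, rng):
        for _ in range(20):
            n_pos, n_neg = rng.integers(3, 15, 2)
            cp = rng.integers(0, n_pos + 1)
            cn = rng.integers(0, n_neg + 1)
            sens = 100.0 * cp / n_pos
            spec = 100.0 * cn / n_neg
            assert mvpa.binary_accuracy(sens, spec, n_pos, n_neg) == \
                pytest.approx(100.0 * (cp + cn) / (n_pos + n_neg))
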