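import itertools

import numpy as np
import pytest

from refugia.grid import EnvStack, RasterGrid, Transform
from refugia.sdm import (
    AdditiveLogisticModel,
    EvaluationScores,
    SREModel,
    auc_score,
    binarize,
    build_ensemble,
    ensemble_combine,
    max_tss,
    qualifying_members,
    sample_pseudo_absences,
)


def pairs_auc(pos, neg):
    """All-pairs counting with half ties."""
    wins = ties = 0
    for p, q in itertools.product(pos, neg):
        if p > q:
            wins += 1
        elif p == q:
            ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def scan_tss(pos, neg):
    """Exhaustive scan over every candidate threshold."""
    scores = np.unique(np.concatenate([pos, neg]))
    cands = np.concatenate(
        [[scores[0] - 1.0], (scores[:-1] + scores[1:]) / 2.0, [scores[-1] + 1.0]]
    )
    best = -2.0
    for t in cands:
        sens = np.mean(np.asarray(pos) >= t)
        spec = np.mean(np.asarray(neg) < t)
        best = max(best, sens + spec - 1.0)
    return best


def flat_env(n=40, seed=0):
    rng = np.random.default_rng(seed)
    t = Transform(86.0, 48.0, 0.01)
    return EnvStack({"x": RasterGrid(rng.random((n, n)), t), "y": RasterGrid(rng.random((n, n)), t)})


class TestSRE:
    def test_percentile_envelope_on_1_to_100(self):
        X = np.arange(1, 101, dtype=float)[:, None]
        m = SREModel(quantile=0.025).fit(X, np.ones(100))
        assert m.lo_[0] == pytest.approx(3.475)
        assert m.hi_[0] == pytest.approx(97.525)
        assert m.predict(np.array([[50.0]]))[0] == 1.0
        assert m.predict(np.array([[200.0]]))[0] == 0.0

    def test_zero_quantile_is_min_max(self):
        X = np.array([[3.0], [9.0], [1.0], [7.0], [5.0]])
        m = SREModel(quantile=0.0).fit(X, np.ones(5))
        assert (m.lo_[0], m.hi_[0]) == (1.0, 9.0)
        # every training vector is inside its own hull
        assert np.all(m.predict(X) == 1.0)

    def test_too_few_presences_rejected(self):
        with pytest.raises(ValueError, match=">= 5"):
            SREModel().fit(np.ones((4, 2)), np.ones(4))


class TestPseudoAbsences:
    def test_contract_distinct_non_presence(self):
        env = flat_env(40)
        pres = np.array([[i, i] for i in range(20)])
        pts = sample_pseudo_absences(env, pres, n=500, seed=1)
        assert len(pts) == 500
        assert len(np.unique(pts, axis=0)) == 500
        pres_set = {tuple(p) for p in pres}
        assert not any(tuple(p) in pres_set for p in pts)

    def test_seed_reproducible(self):
        env = flat_env(30)
        pres = np.array([[0, 0]])
        a = sample_pseudo_absences(env, pres, n=100, seed=42)
        b = sample_pseudo_absences(env, pres, n=100, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_with_replacement_fallback_warns(self):
        env = flat_env(2)  # 4 cells
        pres = np.array([[0, 0]])
        with pytest.warns(UserWarning, match="replacement"):
            pts = sample_pseudo_absences(env, pres, n=50, seed=0)
        assert len(pts) == 50
        assert len(np.unique(pts, axis=0)) <= 3


class TestScores:
    def test_perfect_separation(self):
        assert auc_score([0.9, 0.8], [0.1, 0.2]) == 1.0
        tss, _ = max_tss([0.9, 0.8], [0.1, 0.2])
        assert tss == 1.0

    def test_uninformative_scores(self):
        assert auc_score([0.5] * 4, [0.5] * 6) == 0.5
        tss, _ = max_tss([0.5] * 4, [0.5] * 6)
        assert tss == pytest.approx(0.0)

    def test_worked_eight_point_example(self):
        pos = [0.9, 0.8, 0.6, 0.4]
        neg = [0.7, 0.5, 0.3, 0.2]
        assert auc_score(pos, neg) == pytest.approx(pairs_auc(pos, neg))
        tss, _ = max_tss(pos, neg)
        assert tss == pytest.approx(scan_tss(pos, neg))

    @pytest.mark.parametrize("seed", range(10))
    def test_random_sets_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.choice(np.linspace(0, 1, 11), size=rng.integers(2, 20))
        neg = rng.choice(np.linspace(0, 1, 11), size=rng.integers(2, 20))
        assert auc_score(pos, neg) == pytest.approx(pairs_auc(pos, neg), abs=1e-12)
        tss, thr = max_tss(pos, neg)
        assert tss == pytest.approx(scan_tss(pos, neg), abs=1e-12)
        # the reported threshold achieves the reported TSS
        sens = np.mean(pos >= thr)
        spec = np.mean(neg < thr)
        assert sens + spec - 1.0 == pytest.approx(tss, abs=1e-12)

    def test_auc_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(3)
        pos, neg = rng.random(15), rng.random(25)
        base = auc_score(pos, neg)
        for f in (lambda x: x**3, lambda x: np.exp(2 * x), lambda x: 5 * x - 1):
            assert auc_score(f(pos), f(neg)) == pytest.approx(base, abs=1e-12)


class TestEnsemble:
    def _scores(self, **tss):
        return {
            name: EvaluationScores(auc=[0.95] * 3, tss=[t] * 3, threshold=[0.5] * 3)
            for name, t in tss.items()
        }

    def test_single_qualifier_is_identity(self):
        scores = self._scores(a=0.9, b=0.5)
        assert qualifying_members(scores) == ["a"]
        preds = {"a": np.array([0.2, 0.8])}
        np.testing.assert_allclose(ensemble_combine(preds, {"a": 0.9}), preds["a"])

    def test_equal_weights_give_arithmetic_mean(self):
        preds = {"a": np.array([0.2, 0.8]), "b": np.array([0.4, 0.6])}
        out = ensemble_combine(preds, {"a": 0.85, "b": 0.85})
        np.testing.assert_allclose(out, [0.3, 0.7])

    def test_fallback_to_best_tss_with_warning(self, caplog):
        scores = self._scores(a=0.4, b=0.6)
        scores["a"].auc = scores["b"].auc = [0.7] * 3  # both fail AUC gate too
        with caplog.at_level("WARNING"):
            qual = qualifying_members(scores)
        assert qual == ["b"]
        assert "falling back" in caplog.text

    def test_ensemble_within_member_range(self):
        env = flat_env(20, seed=5)
        rng = np.random.default_rng(5)
        X = np.vstack([rng.random((30, 2)) * 0.3 + 0.5, rng.random((200, 2))])
        y = np.r_[np.ones(30), np.zeros(200)]
        members = {
            "gam": AdditiveLogisticModel().fit(X, y),
            "sre": SREModel().fit(X, y),
        }
        scores = self._scores(gam=0.85, sre=0.82)
        suit, qual, _ = build_ensemble(members, scores, env)
        valid = env.valid_mask()
        rows, cols = np.nonzero(valid)
        grid_x = env.table(rows, cols)
        lo = np.minimum(members["gam"].predict(grid_x), members["sre"].predict(grid_x))
        hi = np.maximum(members["gam"].predict(grid_x), members["sre"].predict(grid_x))
        vals = suit.values[rows, cols]
        assert np.all(vals >= lo - 1e-12) and np.all(vals <= hi + 1e-12)


class TestBinarize:
    def _grid(self, values):
        return RasterGrid(np.asarray(values, dtype=float), Transform(86, 48, 0.1))

    def test_separated_scores_midpoint_threshold(self):
        suit = self._grid([[0.1, 0.9]])
        pooled = np.array([0.65, 0.65, 0.55, 0.55])
        labels = np.array([1, 1, 0, 0])
        binary, thr = binarize(suit, pooled, labels)
        assert thr == pytest.approx(0.60)
        np.testing.assert_array_equal(binary.values, [[0, 1]])

    def test_extremes_classified_consistently(self):
        suit = self._grid([[0.05, 0.95]])
        binary, thr = binarize(suit, np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
        assert binary.values[0, 1] == 1 and binary.values[0, 0] == 0

    def test_recomputing_from_threshold_is_self_consistent(self):
        rng = np.random.default_rng(2)
        suit = self._grid(rng.random((6, 6)))
        pooled = rng.random(40)
        labels = (pooled > 0.5).astype(int)
        binary, thr = binarize(suit, pooled, labels)
        np.testing.assert_array_equal(binary.values, (suit.values >= thr).astype(int))

    def test_degenerate_pooled_scores_warn_all_presence(self):
        suit = self._grid([[0.7, 0.2]])
        with pytest.warns(UserWarning, match="degenerate"):
            binary, thr = binarize(suit, np.full(10, 0.5), np.r_[np.ones(5), np.zeros(5)])
        assert thr == 0.5
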