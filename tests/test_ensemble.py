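import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gapstack.background import TrainingSet
from gapstack.ensemble import (
    TECHNIQUES, EnsembleModel, EvaluationResult, TechniqueFit, best_threshold,
    build_ensemble, cross_evaluate, fit_technique, predict_and_binarize, tss,
)
from gapstack.envstack import EnvStack
from gapstack.grid import Grid


# ---------------------------------------------------------------- tss
class TestTss:
    @pytest.mark.parametrize("conf,expected", [
        ((50, 0, 50, 0), 1.0),
        ((25, 25, 25, 25), 0.0),
        ((40, 10, 30, 20), 0.4),
    ])
    def test_worked_confusion_matrices(self, conf, expected):
        assert tss(*conf) == pytest.approx(expected)

    def test_matches_hand_arithmetic_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            tp, fn, tn, fp = rng.integers(1, 200, size=4)
            assert tss(tp, fn, tn, fp) == pytest.approx(
                tp / (tp + fn) + tn / (tn + fp) - 1.0)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(1, 100), st.integers(0, 100), st.integers(1, 100),
           st.integers(0, 100), st.integers(1, 7))
    def test_invariant_to_positive_scaling(self, tp, fn, tn, fp, k):
        assert tss(k * tp, k * fn, k * tn, k * fp) == pytest.approx(tss(tp, fn, tn, fp))

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            tss(0, 0, 10, 5)
        with pytest.raises(ValueError, match="negative"):
            tss(10, 5, 0, 0)


# ---------------------------------------------------------------- best threshold
def threshold_oracle(scores, labels):
    """Exhaustive scan over all unique score cut-offs."""
    best = (None, -np.inf)
    y = labels.astype(bool)
    for t in np.unique(scores):
        pred = scores > t
        tp = (pred & y).sum(); fn = (~pred & y).sum()
        tn = (~pred & ~y).sum(); fp = (pred & ~y).sum()
        val = tp / (tp + fn) + tn / (tn + fp) - 1
        if val > best[1]:
            best = (t, val)
    return best


class TestBestThreshold:
    def test_perfect_separation_ties_to_smallest_threshold(self):
        scores = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
        labels = np.array([0, 0, 0, 1, 1, 1])
        thr, val = best_threshold(scores, labels)
        assert val == 1.0
        assert thr == pytest.approx(0.3)  # smallest cut-off achieving TSS 1

    @pytest.mark.parametrize("n", [5, 17, 100, 537, 1000])
    def test_matches_exhaustive_scan(self, n):
        rng = np.random.default_rng(n)
        scores = rng.uniform(0, 1, n).round(3)  # force score ties
        labels = (rng.uniform(0, 1, n) < 0.4).astype(int)
        thr, val = best_threshold(scores, labels)
        othr, oval = threshold_oracle(scores, labels)
        assert val == pytest.approx(oval)
        assert thr == pytest.approx(othr)

    def test_inverted_labels_bounded_at_chance(self):
        scores = np.linspace(0, 1, 40)
        labels = (scores < 0.5).astype(int)  # anti-classifier
        _, val = best_threshold(scores, labels)
        assert val <= 1e-12

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            best_threshold(np.array([0.1, 0.9]), np.array([1, 1]))


# ---------------------------------------------------------------- technique fits
def _toy_training(X, y, names=None):
    names = names or [f"f{j}" for j in range(X.shape[1])]
    return TrainingSet(species_id="toy", X=pd.DataFrame(X, columns=names),
                       y=np.asarray(y), presence_xy=np.empty((0, 2)),
                       pa_xy=np.empty((0, 2)), pa_seed=0)


class TestFitTechnique:
    @pytest.mark.parametrize("technique", TECHNIQUES)
    def test_separable_toy_reaches_perfect_training_tss(self, technique):
        X = np.concatenate([np.linspace(-2, -0.5, 30), np.linspace(0.5, 2, 30)])[:, None]
        y = np.repeat([0, 1], 30)
        fit = fit_technique(_toy_training(X, y), technique, seed=0)
        s = fit.predict(X)
        assert np.all((s >= 0) & (s <= 1))
        _, val = best_threshold(s, y)
        assert val == pytest.approx(1.0)

    @pytest.mark.parametrize("technique", TECHNIQUES)
    def test_permuted_labels_have_no_heldout_skill(self, technique):
        # threshold chosen on the training part, TSS scored on held-out rows
        worst = 0.0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((200, 3))
            y = rng.permutation(np.repeat([0, 1], 100))
            fit = fit_technique(_toy_training(X[:140], y[:140]), technique, seed=seed)
            thr, _ = best_threshold(fit.predict(X[:140]), y[:140])
            pred = fit.predict(X[140:]) > thr
            yb = y[140:].astype(bool)
            val = (pred & yb).sum() / yb.sum() + ((~pred) & ~yb).sum() / (~yb).sum() - 1
            worst = max(worst, abs(val))
        assert worst < 0.25

    @pytest.mark.parametrize("technique", ["glm", "gam"])
    def test_constant_feature_column_tolerated(self, technique):
        rng = np.random.default_rng(1)
        X = np.column_stack([rng.standard_normal(60), np.full(60, 3.0)])
        y = (X[:, 0] > 0).astype(int)
        fit = fit_technique(_toy_training(X, y), technique, seed=0)
        s = fit.predict(X)
        assert np.all((s >= 0) & (s <= 1))

    def test_single_class_or_nonfinite_rejected(self):
        X = np.random.default_rng(2).standard_normal((20, 2))
        with pytest.raises(ValueError, match="single-class"):
            fit_technique(_toy_training(X, np.ones(20)), "glm")
        Xbad = X.copy(); Xbad[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_technique(_toy_training(Xbad, np.repeat([0, 1], 10)), "glm")

    def test_unknown_technique_rejected(self):
        X = np.random.default_rng(3).standard_normal((20, 1))
        with pytest.raises(ValueError, match="unknown technique"):
            fit_technique(_toy_training(X, np.repeat([0, 1], 10)), "brt")


# ---------------------------------------------------------------- cross evaluation
def _signal_training(n=120, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 2))
    p = 1 / (1 + np.exp(-3 * X[:, 0]))
    y = (rng.uniform(size=n) < p).astype(int)
    return _toy_training(X, y)


class TestCrossEvaluate:
    def test_five_techniques_ten_runs_give_fifty_results(self):
        evals = cross_evaluate(_signal_training(), n_runs=10, seed=1)
        assert len(evals) == 50
        assert {e.technique for e in evals} == set(TECHNIQUES)
        assert sorted({e.run_index for e in evals}) == list(range(1, 11))

    def test_single_run_single_technique(self):
        evals = cross_evaluate(_signal_training(), techniques=("glm",), n_runs=1, seed=2)
        assert len(evals) == 1
        e = evals[0]
        assert e.tss == pytest.approx(e.sensitivity + e.specificity - 1.0)

    def test_deterministic_per_seed(self):
        a = cross_evaluate(_signal_training(), techniques=("glm", "rf"), n_runs=3, seed=5)
        b = cross_evaluate(_signal_training(), techniques=("glm", "rf"), n_runs=3, seed=5)
        assert [e.tss for e in a] == [e.tss for e in b]
        assert [e.best_threshold for e in a] == [e.best_threshold for e in b]


# ---------------------------------------------------------------- ensemble build
def _fake_evals(mean_by_technique, n_runs=4, seed=0):
    rng = np.random.default_rng(seed)
    evals = []
    for run in range(1, n_runs + 1):
        scores = rng.uniform(0, 1, 30)
        labels = (rng.uniform(0, 1, 30) < 0.5).astype(int)
        for tech, m in mean_by_technique.items():
            evals.append(EvaluationResult(
                technique=tech, run_index=run, tss=m, sensitivity=0.5,
                specificity=0.5, best_threshold=0.5,
                heldout_scores=scores, heldout_labels=labels))
    return evals


class TestBuildEnsemble:
    def test_equal_tss_selects_everyone_with_equal_weights(self):
        training = _signal_training()
        evals = _fake_evals({t: 0.6 for t in TECHNIQUES})
        model = build_ensemble(training, evals, seed=0)
        assert model.selected_members == list(TECHNIQUES)
        for w in model.weights.values():
            assert w == pytest.approx(0.2)

    def test_single_strong_technique_selected_alone(self):
        # means 0.9 + four at 0.1 -> selection threshold 0.26, floor 0.40
        training = _signal_training()
        evals = _fake_evals({"gam": 0.1, "glm": 0.9, "mars": 0.1,
                             "rf": 0.1, "maxent": 0.1})
        model = build_ensemble(training, evals, seed=0)
        assert model.selection_threshold == pytest.approx(0.26)
        assert model.selected_members == ["glm"]

    def test_no_qualifier_falls_back_to_best_with_warning(self):
        training = _signal_training()
        evals = _fake_evals({"gam": 0.2, "glm": 0.35, "rf": 0.2})
        with pytest.warns(UserWarning, match="falling back"):
            model = build_ensemble(training, evals, seed=0)
        assert model.selected_members == ["glm"]

    def test_cutoff_maximizes_pooled_heldout_tss(self):
        training = _signal_training(seed=3)
        evals = cross_evaluate(training, techniques=("glm",), n_runs=4, seed=3)
        model = build_ensemble(training, evals, seed=3)
        pooled_s = np.concatenate([e.heldout_scores for e in evals])
        pooled_y = np.concatenate([e.heldout_labels for e in evals])
        thr, val = best_threshold(pooled_s, pooled_y)
        assert model.cutoff_P == pytest.approx(thr)
        assert model.ensemble_tss == pytest.approx(val)


# ---------------------------------------------------------------- binarization
def _stub_ensemble(suit_values, cutoff, name="v"):
    fit = TechniqueFit(technique="glm", feature_names=[name], seed=0,
                       _predict_fn=lambda Z: np.asarray(suit_values).ravel())
    return EnsembleModel(species_id="s", members={"glm": fit}, weights={"glm": 1.0},
                         technique_mean_tss={"glm": 0.8}, selection_threshold=0.5,
                         tss_floor=0.4, cutoff_P=cutoff, ensemble_tss=0.8,
                         feature_names=[name])


def _env_4x4():
    g = Grid(xmin=0, ymin=0, cell_size=100, nrows=4, ncols=4)
    vals = np.arange(16, dtype=float).reshape(4, 4) / 16.0
    return EnvStack(layers={"v": vals}, season={"v": "annual"}, grid=g), vals


class TestPredictAndBinarize:
    def test_toy_grid_matches_manual_comparison(self):
        env, vals = _env_4x4()
        model = _stub_ensemble(vals, cutoff=0.4)
        out = predict_and_binarize(model, env)
        np.testing.assert_array_equal(out.presence, vals > 0.4)
        assert out.area_km2 == pytest.approx(out.presence.sum() * 0.01)

    def test_suitability_exactly_at_cutoff_is_absent(self):
        env, vals = _env_4x4()
        model = _stub_ensemble(vals, cutoff=float(vals[1, 2]))
        out = predict_and_binarize(model, env)
        assert not out.presence[1, 2]

    def test_everything_below_cutoff_gives_empty_map(self):
        env, vals = _env_4x4()
        out = predict_and_binarize(_stub_ensemble(vals, cutoff=2.0), env)
        assert out.area_km2 == 0.0
        assert np.isnan(out.mean_elevation(vals))

    def test_raising_cutoff_never_grows_the_area(self):
        env, vals = _env_4x4()
        areas = [predict_and_binarize(_stub_ensemble(vals, cutoff=c), env).area_km2
                 for c in np.linspace(0, 1, 11)]
        assert all(a >= b for a, b in zip(areas, areas[1:]))

    def test_missing_feature_layer_rejected(self):
        env, vals = _env_4x4()
        model = _stub_ensemble(vals, cutoff=0.5, name="w")
        with pytest.raises(KeyError, match="w"):
            predict_and_binarize(model, env)
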