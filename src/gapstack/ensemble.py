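"""Five-technique presence/pseudo-absence ensemble with TSS evaluation.

Per species the workflow is: fit GAM, GLM, MARS, RF and MaxEnt-style models
on presence vs pseudo-absence data; evaluate each by the true skill statistic
(TSS = sensitivity + specificity - 1) at its optimal cut-off over 10 random
70/30 splits (5 techniques x 10 runs = 50 TSS values); select techniques
whose mean TSS reaches the mean of all 50 values (and a 0.40 quality floor);
refit the selected techniques on all data; combine them as a TSS-weighted
mean; and binarize the ensemble suitability at the cut-off P that maximizes
TSS on the pooled held-out predictions (present iff suitability > P).

Technique contracts (all return suitability in [0, 1], deterministic per seed):

* glm    — logistic regression on linear + quadratic terms;
* gam    — additive model: logistic regression on per-feature B-spline bases;
* mars   — adaptive piecewise-linear (hinge) basis at quantile knots, pruned
           by L1-regularized logistic regression;
* rf     — bagged decision trees (random forest), probability output;
* maxent — the presence/background exponential model approximated as a
           class-balanced regularized logistic regression on linear +
           quadratic features, regularization chosen by a small fixed C
           sweep on an internal held-out split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.preprocessing import SplineTransformer, StandardScaler

from .background import TrainingSet
from .envstack import EnvStack
from .grid import Grid

__all__ = [
    "TECHNIQUES", "TechniqueFit", "EvaluationResult", "EnsembleModel",
    "BinaryDistribution", "tss", "best_threshold", "fit_technique",
    "cross_evaluate", "build_ensemble", "predict_and_binarize",
]

TECHNIQUES = ("gam", "glm", "mars", "rf", "maxent")


# --------------------------------------------------------------------------- scoring
def tss(tp: float, fn: float, tn: float, fp: float) -> float:
    """True skill statistic: sensitivity + specificity - 1, in [-1, 1].

    Invariant to scaling the confusion matrix; requires both classes present.
    """
    if tp + fn <= 0:
        raise ValueError("empty positive class (TP + FN = 0)")
    if tn + fp <= 0:
        raise ValueError("empty negative class (TN + FP = 0)")
    return tp / (tp + fn) + tn / (tn + fp) - 1.0


def best_threshold(scores: np.ndarray, labels: np.ndarray,
                   grid: np.ndarray | None = None) -> tuple[float, float]:
    """Cut-off maximizing TSS when predicting present for score > threshold.

    Candidates default to all unique score values; ties take the smallest
    threshold.  Returns (threshold, tss_at_threshold).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    cand = np.unique(s if grid is None else np.asarray(grid, dtype=float))
    pos = np.sort(s[y == 1])
    neg = np.sort(s[y == 0])
    tp = n_pos - np.searchsorted(pos, cand, side="right")
    fp = n_neg - np.searchsorted(neg, cand, side="right")
    tss_vals = tp / n_pos + (n_neg - fp) / n_neg - 1.0
    i = int(np.argmax(tss_vals))  # first max = smallest threshold (cand sorted)
    return float(cand[i]), float(tss_vals[i])


def _confusion(scores: np.ndarray, labels: np.ndarray, thr: float) -> tuple[int, int, int, int]:
    pred = scores > thr
    y = np.asarray(labels).astype(bool)
    tp = int((pred & y).sum())
    fn = int((~pred & y).sum())
    tn = int((~pred & ~y).sum())
    fp = int((pred & ~y).sum())
    return tp, fn, tn, fp


# --------------------------------------------------------------------------- features
def _quad(X: np.ndarray) -> np.ndarray:
    return np.hstack([X, X ** 2])


def _hinges(X: np.ndarray, knots: list[np.ndarray]) -> np.ndarray:
    cols = []
    for j in range(X.shape[1]):
        for k in knots[j]:
            cols.append(np.maximum(X[:, j] - k, 0.0))
            cols.append(np.maximum(k - X[:, j], 0.0))
    return np.column_stack(cols) if cols else np.empty((len(X), 0))


@dataclass
class TechniqueFit:
    """One fitted technique: maps a feature matrix to suitability in [0, 1]."""

    technique: str
    feature_names: list[str]
    seed: int
    _predict_fn: object = field(repr=False)

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names].to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        p = self._predict_fn(X)
        return np.clip(p, 0.0, 1.0)


def _fit_arrays(X: np.ndarray, y: np.ndarray, technique: str, seed: int):
    """Fit one technique on raw arrays; returns a predict(X)->p callable."""
    keep = np.ptp(X, axis=0) > 0
    if not keep.any():
        prev = float(np.mean(y))
        return lambda Z: np.full(len(Z), prev)
    Xk = X[:, keep]

    if technique == "glm":
        model = LogisticRegression(C=10.0, max_iter=2000)
        scaler = StandardScaler().fit(_quad(Xk))
        model.fit(scaler.transform(_quad(Xk)), y)
        return lambda Z: model.predict_proba(scaler.transform(_quad(Z[:, keep])))[:, 1]

    if technique == "gam":
        spline = SplineTransformer(n_knots=5, degree=3, include_bias=False,
                                   knots="quantile").fit(Xk)
        model = LogisticRegression(C=1.0, max_iter=2000)
        scaler = StandardScaler().fit(spline.transform(Xk))
        model.fit(scaler.transform(spline.transform(Xk)), y)
        return lambda Z: model.predict_proba(
            scaler.transform(spline.transform(Z[:, keep])))[:, 1]

    if technique == "mars":
        qs = np.linspace(0.1, 0.9, 5)
        knots = [np.unique(np.quantile(Xk[:, j], qs)) for j in range(Xk.shape[1])]
        H = _hinges(Xk, knots)
        scaler = StandardScaler().fit(H)
        model = LogisticRegression(l1_ratio=1.0, solver="liblinear", C=1.0,
                                   random_state=seed, max_iter=2000)
        model.fit(scaler.transform(H), y)
        return lambda Z: model.predict_proba(
            scaler.transform(_hinges(Z[:, keep], knots)))[:, 1]

    if technique == "rf":
        model = RandomForestClassifier(n_estimators=100, min_samples_leaf=2,
                                       random_state=seed, n_jobs=1)
        model.fit(Xk, y)
        return lambda Z: model.predict_proba(Z[:, keep])[:, 1]

    if technique == "maxent":
        # regularized logistic against the background class, class-balanced,
        # regularization strength picked on an internal 70/30 split by TSS
        Q = _quad(Xk)
        scaler = StandardScaler().fit(Q)
        Qs = scaler.transform(Q)
        c_grid = (0.1, 1.0, 10.0)
        best_c, best_t = c_grid[0], -np.inf
        sss = StratifiedShuffleSplit(n_splits=1, train_size=0.7, random_state=seed)
        (tr, te), = sss.split(Qs, y)
        if len(np.unique(y[tr])) == 2 and len(np.unique(y[te])) == 2:
            for c in c_grid:
                m = LogisticRegression(C=c, class_weight="balanced", max_iter=2000)
                m.fit(Qs[tr], y[tr])
                _, t = best_threshold(m.predict_proba(Qs[te])[:, 1], y[te])
                if t > best_t:
                    best_c, best_t = c, t
        model = LogisticRegression(C=best_c, class_weight="balanced", max_iter=2000)
        model.fit(Qs, y)
        return lambda Z: model.predict_proba(scaler.transform(_quad(Z[:, keep])))[:, 1]

    raise ValueError(f"unknown technique {technique!r}; expected one of {TECHNIQUES}")


def fit_technique(training: TrainingSet, technique: str, seed: int = 0) -> TechniqueFit:
    """Fit one modeling technique on a full training set."""
    X = training.X.to_numpy(dtype=float)
    y = np.asarray(training.y).astype(int)
    if not np.isfinite(X).all():
        raise ValueError(f"{training.species_id}: non-finite feature values")
    if len(np.unique(y)) < 2:
        raise ValueError(f"{training.species_id}: single-class training data")
    fn = _fit_arrays(X, y, technique, seed)
    return TechniqueFit(technique=technique, feature_names=training.feature_names,
                        seed=seed, _predict_fn=fn)


# --------------------------------------------------------------------------- evaluation
@dataclass
class EvaluationResult:
    technique: str
    run_index: int                       # 1-based
    tss: float
    sensitivity: float
    specificity: float
    best_threshold: float
    heldout_scores: np.ndarray = field(repr=False)
    heldout_labels: np.ndarray = field(repr=False)


def cross_evaluate(training: TrainingSet,
                   techniques: tuple[str, ...] = TECHNIQUES,
                   n_runs: int = 10,
                   split_fraction: float = 0.7,
                   seed: int = 0) -> list[EvaluationResult]:
    """Repeated stratified split evaluation: for each run, fit every technique
    on the train part and score TSS at the optimal cut-off on the held-out
    part.  len(techniques) x n_runs results (50 with the defaults)."""
    for t in techniques:
        if t not in TECHNIQUES:
            raise ValueError(f"unknown technique {t!r}; expected one of {TECHNIQUES}")
    X = training.X.to_numpy(dtype=float)
    y = np.asarray(training.y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError(f"{training.species_id}: single-class training data")
    results: list[EvaluationResult] = []
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 7])
    run_seeds = [int(s) for s in ss.generate_state(n_runs * (len(techniques) + 1)) % (2 ** 31)]
    for run in range(1, n_runs + 1):
        split_seed = run_seeds[(run - 1) * (len(techniques) + 1)]
        sss = StratifiedShuffleSplit(n_splits=1, train_size=split_fraction,
                                     random_state=split_seed)
        (tr, te), = sss.split(X, y)
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            raise ValueError(f"run {run}: split left a single-class partition")
        for j, tech in enumerate(techniques):
            fit_seed = run_seeds[(run - 1) * (len(techniques) + 1) + 1 + j]
            fn = _fit_arrays(X[tr], y[tr], tech, fit_seed)
            s = np.clip(fn(X[te]), 0.0, 1.0)
            thr, tval = best_threshold(s, y[te])
            tp, fnn, tn, fp = _confusion(s, y[te], thr)
            results.append(EvaluationResult(
                technique=tech, run_index=run, tss=tval,
                sensitivity=tp / (tp + fnn), specificity=tn / (tn + fp),
                best_threshold=thr, heldout_scores=s, heldout_labels=y[te].copy()))
    return results


# --------------------------------------------------------------------------- ensemble
@dataclass
class EnsembleModel:
    species_id: str
    members: dict[str, TechniqueFit]         # selected technique -> refit on all data
    weights: dict[str, float]                # normalized combination weights
    technique_mean_tss: dict[str, float]
    selection_threshold: float               # mean TSS over all evaluations
    tss_floor: float
    cutoff_P: float
    ensemble_tss: float
    feature_names: list[str]

    @property
    def selected_members(self) -> list[str]:
        return list(self.members)

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Weighted-mean suitability of the selected members, in [0, 1]."""
        out = None
        for tech, fit in self.members.items():
            p = self.weights[tech] * fit.predict(X)
            out = p if out is None else out + p
        return np.clip(out, 0.0, 1.0)


def build_ensemble(training: TrainingSet,
                   evals: list[EvaluationResult],
                   seed: int = 0,
                   tss_floor: float = 0.40,
                   combination: str = "tss_weighted") -> EnsembleModel:
    """Mean-TSS member selection, refit on all data, TSS-weighted combination.

    The selection threshold is the mean of all evaluation TSS values; a
    technique joins the ensemble iff its own mean TSS reaches that threshold
    and exceeds the quality floor.  If nothing qualifies, the single best
    technique is used (with a warning).  The binarization cut-off P and the
    reported ensemble TSS come from the pooled held-out predictions.
    """
    if not evals:
        raise ValueError("need at least one evaluation result")
    if combination not in ("mean", "tss_weighted"):
        raise ValueError(f"unknown combination rule {combination!r}")
    order: list[str] = []
    for ev in evals:
        if ev.technique not in order:
            order.append(ev.technique)
    mean_tss = {t: float(np.mean([e.tss for e in evals if e.technique == t]))
                for t in order}
    selection_threshold = float(np.mean([e.tss for e in evals]))
    selected = [t for t in order
                if mean_tss[t] >= selection_threshold and mean_tss[t] > tss_floor]
    if not selected:
        best = max(order, key=lambda t: mean_tss[t])
        warnings.warn(f"{training.species_id}: no technique passed member selection; "
                      f"falling back to best single technique {best!r}", stacklevel=2)
        selected = [best]

    if combination == "mean":
        weights = {t: 1.0 / len(selected) for t in selected}
    else:
        raw = {t: max(mean_tss[t], 1e-6) for t in selected}
        tot = sum(raw.values())
        weights = {t: w / tot for t, w in raw.items()}

    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 11])
    refit_seeds = {t: int(s) for t, s in zip(selected, ss.generate_state(len(selected)) % (2 ** 31))}
    members = {t: fit_technique(training, t, seed=refit_seeds[t]) for t in selected}

    # pooled held-out ensemble predictions: per run, combine the selected
    # techniques' held-out scores (splits are shared across techniques)
    runs = sorted({e.run_index for e in evals})
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    by_key = {(e.technique, e.run_index): e for e in evals}
    for r in runs:
        have = [t for t in selected if (t, r) in by_key]
        if not have:
            continue
        wtot = sum(weights[t] for t in have)
        s = sum(weights[t] * by_key[(t, r)].heldout_scores for t in have) / wtot
        pooled_scores.append(s)
        pooled_labels.append(by_key[(have[0], r)].heldout_labels)
    scores = np.concatenate(pooled_scores)
    labels = np.concatenate(pooled_labels)
    cutoff_P, ensemble_tss = best_threshold(scores, labels)

    return EnsembleModel(species_id=training.species_id, members=members,
                         weights=weights, technique_mean_tss=mean_tss,
                         selection_threshold=selection_threshold, tss_floor=tss_floor,
                         cutoff_P=cutoff_P, ensemble_tss=ensemble_tss,
                         feature_names=training.feature_names)


# --------------------------------------------------------------------------- prediction
@dataclass
class BinaryDistribution:
    species_id: str
    scenario: str | None
    presence: np.ndarray            # bool raster
    suitability: np.ndarray
    grid: Grid
    cutoff_P: float

    @property
    def area_km2(self) -> float:
        return float(self.presence.sum()) * self.grid.cell_area_km2

    def mean_elevation(self, elevation: np.ndarray) -> float:
        if not self.presence.any():
            return float("nan")
        return float(elevation[self.presence].mean())


def predict_and_binarize(ensemble: EnsembleModel, env: EnvStack,
                         scenario: str | None = None) -> BinaryDistribution:
    """Ensemble suitability over the whole grid, binarized strictly above the
    cut-off P (a cell with suitability exactly P is absent)."""
    missing = [f for f in ensemble.feature_names if f not in env.layers]
    if missing:
        raise KeyError(f"{ensemble.species_id}: feature layers missing from stack: {missing}")
    X = pd.DataFrame({f: env.layers[f].ravel() for f in ensemble.feature_names})
    suit = ensemble.predict(X).reshape(env.grid.shape)
    presence = suit > ensemble.cutoff_P
    return BinaryDistribution(species_id=ensemble.species_id, scenario=scenario,
                              presence=presence, suitability=suit,
                              grid=env.grid, cutoff_P=ensemble.cutoff_P)
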