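"""Per-species ensemble distribution modelling.

The workflow mirrors standard ensemble SDM practice: random pseudo-absence
generation (1000 points per species), repeated stratified 75/25
train/validation splits (10 repetitions), member scoring by AUC and the
true skill statistic (TSS = sensitivity + specificity - 1 maximized over
thresholds), a skill-gated weighted-mean ensemble (members enter only with
mean AUC > 0.9 and mean TSS > 0.8; weights are mean TSS), and conversion
of the continuous ensemble suitability to presence/absence at the max-TSS
threshold of the pooled ensemble validation scores.

Members satisfy a small plug-in contract (``fit(X, y)``/``predict(X)`` in
[0, 1]); three are provided natively: a surface range envelope (SRE), a
GAM-style additive-logistic learner, and a gradient-boosted tree ensemble.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler

from .grid import EnvStack, RasterGrid

logger = logging.getLogger(__name__)

__all__ = [
    "AUC_GATE",
    "TSS_GATE",
    "SREModel",
    "AdditiveLogisticModel",
    "TreeEnsembleModel",
    "MEMBER_FACTORIES",
    "sample_pseudo_absences",
    "auc_score",
    "max_tss",
    "EvaluationScores",
    "evaluate_member",
    "cross_validate_members",
    "build_ensemble",
    "binarize",
    "SpeciesRangeMaps",
    "fit_species",
]

AUC_GATE = 0.9
TSS_GATE = 0.8
N_PSEUDO_ABSENCES = 1000
N_REPETITIONS = 10
TEST_FRACTION = 0.25


# ---------------------------------------------------------------------------
# Member models (plug-in contract: fit(X, y) -> self; predict(X) -> [0, 1])
# ---------------------------------------------------------------------------

class SREModel:
    """Surface range envelope: per-variable percentile box on presences.

    The envelope for each variable is the [q, 1-q] empirical percentile
    interval (linear interpolation) of the presence values; a point scores
    1 iff every variable falls inside its interval, else 0. Absences are
    ignored during fitting.
    """

    def __init__(self, quantile: float = 0.025, seed: int | None = None):
        if not 0.0 <= quantile < 0.5:
            raise ValueError("quantile must be in [0, 0.5)")
        self.quantile = quantile
        self.lo_: np.ndarray | None = None
        self.hi_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray):
        pres = np.asarray(X, dtype=float)[np.asarray(y) == 1]
        if len(pres) < 5:
            raise ValueError("SRE needs >= 5 presence vectors")
        self.lo_ = np.quantile(pres, self.quantile, axis=0)
        self.hi_ = np.quantile(pres, 1.0 - self.quantile, axis=0)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        inside = (X >= self.lo_) & (X <= self.hi_)
        return inside.all(axis=1).astype(float)


class AdditiveLogisticModel:
    """GAM-style additive logistic learner.

    Each covariate enters through a smooth one-dimensional basis (linear
    term plus Gaussian bumps anchored at training quantiles), and the
    logistic fit over the summed bases is mildly ridge-penalized. Local
    bases let the model express narrow unimodal responses without driving
    global coefficients — and hence predicted probabilities — to
    saturation, so downstream threshold selection stays meaningful.
    """

    def __init__(
        self,
        seed: int | None = None,
        n_centers: int = 16,
        C: float = 2.0,
        width_factor: float = 1.5,
    ):
        self.n_centers = n_centers
        self.width_factor = width_factor
        self.scaler_ = StandardScaler()
        self.clf_ = LogisticRegression(max_iter=5000, C=C, class_weight="balanced")
        self.centers_: np.ndarray | None = None
        self.widths_: np.ndarray | None = None

    def _basis(self, X):
        X = np.asarray(X, dtype=float)
        cols = [X]
        for j in range(X.shape[1]):
            c = self.centers_[j]
            h = self.widths_[j]
            cols.append(np.exp(-0.5 * ((X[:, j : j + 1] - c[None, :]) / h[None, :]) ** 2))
        return np.hstack(cols)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        qs = np.linspace(0.05, 0.95, self.n_centers)
        self.centers_ = np.quantile(X, qs, axis=0).T  # (n_vars, n_centers)
        widths = np.diff(self.centers_, axis=1)
        widths = np.hstack([widths, widths[:, -1:]]) * self.width_factor
        self.widths_ = np.maximum(widths, 1e-9)
        Z = self.scaler_.fit_transform(self._basis(X))
        self.clf_.fit(Z, np.asarray(y))
        return self

    def predict(self, X) -> np.ndarray:
        Z = self.scaler_.transform(self._basis(X))
        return self.clf_.predict_proba(Z)[:, 1]


class TreeEnsembleModel:
    """Gradient-boosted tree member; suitability = predicted class probability.

    Boosted shallow trees fit sharp niche edges from few presences better
    than bagged deep trees, at the cost of needing explicit imbalance
    weighting (``scale_pos_weight``).
    """

    def __init__(self, seed: int | None = None, n_estimators: int = 200):
        import xgboost as xgb

        self._xgb = xgb
        self.n_estimators = n_estimators
        self.seed = 0 if seed is None else int(seed) % (2**31)
        self.clf_ = None

    def fit(self, X, y):
        y = np.asarray(y)
        n_pos = max(int((y == 1).sum()), 1)
        n_neg = max(int((y == 0).sum()), 1)
        self.clf_ = self._xgb.XGBClassifier(
            n_estimators=self.n_estimators,
            max_depth=3,
            learning_rate=0.1,
            scale_pos_weight=n_neg / n_pos,
            random_state=self.seed,
            n_jobs=1,
            verbosity=0,
        )
        self.clf_.fit(np.asarray(X, dtype=float), y)
        return self

    def predict(self, X) -> np.ndarray:
        return np.clip(self.clf_.predict_proba(np.asarray(X, dtype=float))[:, 1], 0.0, 1.0)


MEMBER_FACTORIES = {
    "SRE": lambda seed: SREModel(seed=seed),
    "additive-logistic": lambda seed: AdditiveLogisticModel(seed=seed),
    "tree-ensemble": lambda seed: TreeEnsembleModel(seed=seed),
}


# ---------------------------------------------------------------------------
# Pseudo-absences
# ---------------------------------------------------------------------------

def sample_pseudo_absences(
    env: EnvStack,
    presence_cells: np.ndarray,
    n: int = N_PSEUDO_ABSENCES,
    seed: int = 0,
) -> np.ndarray:
    """(n, 2) array of (row, col) background cells, uniform over valid
    non-presence cells, without replacement while possible.

    If fewer candidate cells exist than requested, sampling falls back to
    with-replacement and a warning is emitted.
    """
    rng = np.random.default_rng(seed)
    valid = env.valid_mask()
    cand = valid.copy()
    pres = np.asarray(presence_cells, dtype=int)
    if len(pres):
        cand[pres[:, 0], pres[:, 1]] = False
    rows, cols = np.nonzero(cand)
    if len(rows) == 0:
        raise ValueError("no valid non-presence cell to sample from")
    if len(rows) >= n:
        idx = rng.choice(len(rows), size=n, replace=False)
    else:
        warnings.warn(
            f"only {len(rows)} candidate cells for {n} pseudo-absences; "
            "sampling with replacement"
        )
        idx = rng.choice(len(rows), size=n, replace=True)
    return np.column_stack([rows[idx], cols[idx]])


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def auc_score(pos_scores, neg_scores) -> float:
    """P(random presence outscores random absence), ties counting 1/2.

    Computed via the rank-sum identity with midranks.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def _tss_candidates(scores: np.ndarray) -> np.ndarray:
    u = np.unique(scores)
    mids = (u[:-1] + u[1:]) / 2.0
    return np.concatenate([[u[0] - 1.0], mids, [u[-1] + 1.0]])


def max_tss(pos_scores, neg_scores) -> tuple[float, float]:
    """(max TSS, threshold) over candidate cuts.

    Candidates are the midpoints of adjacent unique scores plus the two
    extremes (all-presence / all-absence cuts); presence is score >=
    threshold. Ties among maximizing candidates resolve to the middle
    tying candidate, so the reported cut always achieves the maximum.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be non-empty")
    cands = _tss_candidates(np.concatenate([pos, neg]))
    sens = (pos[:, None] >= cands[None, :]).mean(axis=0)
    spec = (neg[:, None] < cands[None, :]).mean(axis=0)
    tss = sens + spec - 1.0
    best = tss.max()
    at_best = np.flatnonzero(np.isclose(tss, best, rtol=0, atol=1e-12))
    return float(best), float(cands[at_best[len(at_best) // 2]])


@dataclass
class EvaluationScores:
    """Per-repetition AUC / max-TSS / threshold plus their means."""

    auc: list[float] = field(default_factory=list)
    tss: list[float] = field(default_factory=list)
    threshold: list[float] = field(default_factory=list)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.auc)) if self.auc else np.nan

    @property
    def mean_tss(self) -> float:
        return float(np.mean(self.tss)) if self.tss else np.nan


def evaluate_member(member, X_test, y_test) -> tuple[float, float, float]:
    """(AUC, max TSS, threshold) of a fitted member on one test split."""
    y_test = np.asarray(y_test)
    if len(np.unique(y_test)) < 2:
        raise ValueError("single-class test split")
    scores = member.predict(X_test)
    pos, neg = scores[y_test == 1], scores[y_test == 0]
    auc = auc_score(pos, neg)
    tss, thr = max_tss(pos, neg)
    return auc, tss, thr


def cross_validate_members(
    member_names: list[str],
    X: np.ndarray,
    y: np.ndarray,
    base_seed: int,
    n_repetitions: int = N_REPETITIONS,
    test_fraction: float = TEST_FRACTION,
):
    """Repeated stratified split evaluation of every member.

    Returns ``(scores, held_out)`` where ``scores`` maps member name to
    :class:`EvaluationScores` and ``held_out`` retains each repetition's
    test labels and per-member test predictions (needed later to pool
    ensemble validation scores). Split seeds are ``base_seed + rep``.
    """
    scores = {name: EvaluationScores() for name in member_names}
    held_out = []
    for rep in range(n_repetitions):
        seed = int(base_seed) + rep
        idx_train, idx_test = train_test_split(
            np.arange(len(y)),
            test_size=test_fraction,
            random_state=seed % (2**31),
            stratify=y,
        )
        if len(np.unique(y[idx_test])) < 2 or len(np.unique(y[idx_train])) < 2:
            warnings.warn(f"repetition {rep}: single-class split skipped")
            continue
        rep_preds = {}
        for name in member_names:
            member = MEMBER_FACTORIES[name](seed)
            try:
                member.fit(X[idx_train], y[idx_train])
            except ValueError as e:
                warnings.warn(f"repetition {rep}: member {name} not fitted ({e})")
                continue
            pred = member.predict(X[idx_test])
            rep_preds[name] = pred
            pos, neg = pred[y[idx_test] == 1], pred[y[idx_test] == 0]
            a = auc_score(pos, neg)
            t, thr = max_tss(pos, neg)
            scores[name].auc.append(a)
            scores[name].tss.append(t)
            scores[name].threshold.append(thr)
        held_out.append({"y": y[idx_test], "preds": rep_preds})
    return scores, held_out


# ---------------------------------------------------------------------------
# Ensemble
# ---------------------------------------------------------------------------

def qualifying_members(
    scores: dict[str, EvaluationScores],
    auc_gate: float = AUC_GATE,
    tss_gate: float = TSS_GATE,
) -> list[str]:
    """Members whose mean AUC and mean TSS clear the gates; if none do,
    fall back to the single best-TSS member (logged prominently)."""
    qual = [
        n for n, s in scores.items() if s.mean_auc > auc_gate and s.mean_tss > tss_gate
    ]
    if not qual:
        best = max(
            scores,
            key=lambda n: -np.inf if np.isnan(scores[n].mean_tss) else scores[n].mean_tss,
        )
        logger.warning(
            "no member cleared AUC > %.2f and TSS > %.2f; falling back to "
            "best-TSS member %r (TSS=%.3f)",
            auc_gate, tss_gate, best, scores[best].mean_tss,
        )
        qual = [best]
    return qual


def ensemble_combine(preds: dict[str, np.ndarray], weights: dict[str, float]) -> np.ndarray:
    """TSS-weighted mean of member predictions."""
    w_total = sum(weights.values())
    out = np.zeros_like(next(iter(preds.values())), dtype=float)
    for name, p in preds.items():
        out += weights[name] * np.asarray(p, dtype=float)
    return out / w_total


def build_ensemble(
    fitted_members: dict[str, object],
    scores: dict[str, EvaluationScores],
    env: EnvStack,
    auc_gate: float = AUC_GATE,
    tss_gate: float = TSS_GATE,
) -> tuple[RasterGrid, list[str], dict[str, float]]:
    """Weighted-mean ensemble suitability over the grid.

    Returns (suitability grid, qualifying member names, weights).
    """
    qual = qualifying_members(scores, auc_gate, tss_gate)
    weights = {n: max(scores[n].mean_tss, 1e-9) for n in qual}
    valid = env.valid_mask()
    rows, cols = np.nonzero(valid)
    X = env.table(rows, cols)
    preds = {n: fitted_members[n].predict(X) for n in qual}
    combined = ensemble_combine(preds, weights)
    vals = np.zeros(env.template.shape, dtype=float)
    vals[rows, cols] = combined
    return env.template.copy_with(vals, valid), qual, weights


def binarize(
    suitability: RasterGrid,
    pooled_scores: np.ndarray,
    pooled_labels: np.ndarray,
) -> tuple[RasterGrid, float]:
    """Presence/absence map at the max-TSS cut of the pooled (across
    repetitions) ensemble validation scores; presence iff suitability >=
    threshold."""
    pooled_scores = np.asarray(pooled_scores, dtype=float)
    pooled_labels = np.asarray(pooled_labels)
    if np.unique(pooled_scores).size == 1:
        warnings.warn("degenerate pooled scores (all equal): all-presence map")
        thr = float(pooled_scores[0])
    else:
        _, thr = max_tss(pooled_scores[pooled_labels == 1], pooled_scores[pooled_labels == 0])
    binary = (suitability.values >= thr) & suitability.mask
    return suitability.copy_with(binary.astype(int), suitability.mask), thr


# ---------------------------------------------------------------------------
# Per-species driver
# ---------------------------------------------------------------------------

@dataclass
class SpeciesRangeMaps:
    species_id: str
    suitability_current: RasterGrid
    suitability_future: RasterGrid
    binary_current: RasterGrid
    binary_future: RasterGrid
    ensemble_threshold: float
    member_scores: dict[str, EvaluationScores]
    qualifying: list[str]
    weights: dict[str, float]


def presence_cells_from_points(env: EnvStack, lons, lats) -> np.ndarray:
    """Unique (row, col) presence cells for occurrence points inside the
    grid and on valid cells."""
    t = env.template.transform
    rows, cols = t.index_of(np.asarray(lons), np.asarray(lats))
    n_rows, n_cols = env.template.shape
    ok = (rows >= 0) & (rows < n_rows) & (cols >= 0) & (cols < n_cols)
    rows, cols = rows[ok], cols[ok]
    valid = env.valid_mask()
    ok = valid[rows, cols]
    cells = np.unique(np.column_stack([rows[ok], cols[ok]]), axis=0)
    return cells


def fit_species(
    species_id: str,
    env_current: EnvStack,
    env_future: EnvStack,
    lons,
    lats,
    seed: int,
    member_names: list[str] | None = None,
    n_pseudo_absences: int = N_PSEUDO_ABSENCES,
    n_repetitions: int = N_REPETITIONS,
    auc_gate: float = AUC_GATE,
    tss_gate: float = TSS_GATE,
) -> SpeciesRangeMaps:
    """Full per-species workflow: pseudo-absences, member cross-validation,
    gated weighted-mean ensemble, max-TSS binarization of both scenarios
    (one threshold, estimated under the current scenario)."""
    member_names = member_names or list(MEMBER_FACTORIES)
    pres = presence_cells_from_points(env_current, lons, lats)
    if len(pres) < 5:
        raise ValueError(f"{species_id}: fewer than 5 presence cells on the grid")
    absn = sample_pseudo_absences(env_current, pres, n_pseudo_absences, seed)
    cells = np.vstack([pres, absn])
    y = np.concatenate([np.ones(len(pres), dtype=int), np.zeros(len(absn), dtype=int)])
    X = env_current.table(cells[:, 0], cells[:, 1])

    scores, held_out = cross_validate_members(
        member_names, X, y, base_seed=seed, n_repetitions=n_repetitions
    )

    fitted = {n: MEMBER_FACTORIES[n](seed).fit(X, y) for n in member_names}
    suit_cur, qual, weights = build_ensemble(fitted, scores, env_current, auc_gate, tss_gate)
    suit_fut, _, _ = build_ensemble(
        fitted, {n: scores[n] for n in member_names}, env_future, auc_gate, tss_gate
    )

    usable = [h for h in held_out if all(n in h["preds"] for n in qual)]
    if not usable:
        raise ValueError(f"{species_id}: no validation repetition covers the ensemble members")
    pooled_scores = np.concatenate(
        [ensemble_combine({n: h["preds"][n] for n in qual}, weights) for h in usable]
    )
    pooled_labels = np.concatenate([h["y"] for h in usable])
    bin_cur, thr = binarize(suit_cur, pooled_scores, pooled_labels)
    bin_fut = suit_fut.copy_with(
        ((suit_fut.values >= thr) & suit_fut.mask).astype(int), suit_fut.mask
    )
    return SpeciesRangeMaps(
        species_id=species_id,
        suitability_current=suit_cur,
        suitability_future=suit_fut,
        binary_current=bin_cur,
        binary_future=bin_fut,
        ensemble_threshold=thr,
        member_scores=scores,
        qualifying=qual,
        weights=weights,
    )
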