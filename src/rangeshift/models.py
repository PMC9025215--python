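"""Presence-background suitability models under spatial-block cross-validation.

Four model families are provided:

* :func:`fit_maxent` — a maxnet-style learner: linear/quadratic/hinge
  features, L1-penalized infinitely-weighted logistic regression, and
  complementary log-log output;
* :func:`fit_tree_model` — random forest ("RF") or boosted regression
  trees ("BRT") with permutation-importance variable reduction and a small
  hyperparameter search;
* :class:`BootstrapEnsembleModel` — a bagged tree learner exposing
  per-cell prediction spread as ``uncertainty`` (stands in for any member
  model that reports per-cell uncertainty).

Everything predicts suitability in [0, 1] from an (n, nvars) environmental
matrix in a fixed variable order.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import warnings

import numpy as np
import pandas as pd
import shapely
from scipy.special import expit
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from rangeshift.evaluation import score_predictions, threshold_maxSSS
from rangeshift.grid import GridSpec
from rangeshift.occurrence_prep import StudyArea

logger = logging.getLogger(__name__)


class SuitabilityModel:
    """Contract for a fitted presence-background learner.

    Concrete models expose ``algorithm`` (label), ``variable_names`` (raw
    variable order expected by ``predict``), optional ``importance``
    (percent per variable, summing to ~100), ``predict`` into [0, 1] and an
    optional per-cell ``uncertainty``.
    """

    algorithm = "base"
    importance = None

    def predict(self, X: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def uncertainty(self, X: np.ndarray) -> np.ndarray | None:
        return None


# ---------------------------------------------------------------------------
# background sampling and spatial blocks


def make_background(
    study_area: StudyArea,
    grid: GridSpec,
    n: int = 30_000,
    seed: int = 0,
    data_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Uniform random background points inside the study area.

    Points fall in grid cells with data (``data_mask``, default all cells)
    whose centers lie inside the study-area polygon, jittered uniformly
    within each cell. Deterministic given ``seed``.
    """
    lon, lat = grid.lonlat_mesh()
    inside = shapely.contains_xy(study_area.polygon, lon.ravel(), lat.ravel())
    if data_mask is not None:
        inside &= np.asarray(data_mask, dtype=bool).ravel()
    candidates = np.flatnonzero(inside)
    if candidates.size == 0:
        raise ValueError("degenerate study area: no grid cells available for background")
    rng = np.random.default_rng(seed)
    idx = rng.choice(candidates, size=n, replace=True)
    row, col = np.unravel_index(idx, grid.shape)
    clon, clat = grid.cell_center(row, col)
    clon = clon + rng.uniform(-0.5, 0.5, n) * grid.cellsize
    clat = clat + rng.uniform(-0.5, 0.5, n) * grid.cellsize
    return pd.DataFrame({"lon": clon, "lat": clat})


def spatial_blocks(presences: pd.DataFrame, background: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """2x2 spatial block assignment (ids 1..4) for presences and background.

    Blocks split at the median presence longitude and, within each
    longitudinal half, at the median latitude of that half's presences;
    the same borders are applied to the background points.
    """
    plon = presences["lon"].to_numpy(dtype=float)
    plat = presences["lat"].to_numpy(dtype=float)
    if len(np.unique(np.column_stack([plon, plat]), axis=0)) < 4:
        raise ValueError("need at least 4 non-collocated presences for spatial blocks")
    lon_split = float(np.median(plon))
    west = plon < lon_split
    if not west.any() or west.all():
        raise ValueError("degenerate longitudinal split (all presences at one longitude?)")
    lat_split_w = float(np.median(plat[west]))
    lat_split_e = float(np.median(plat[~west]))

    def assign(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        w = lon < lon_split
        south = np.where(w, lat < lat_split_w, lat < lat_split_e)
        return np.where(w, np.where(south, 1, 2), np.where(south, 3, 4))

    pres_blocks = assign(plon, plat)
    if len(np.unique(pres_blocks)) < 4:
        raise ValueError("spatial blocking produced an empty presence block")
    bg_blocks = assign(background["lon"].to_numpy(dtype=float), background["lat"].to_numpy(dtype=float))
    return pres_blocks, bg_blocks


# ---------------------------------------------------------------------------
# maxnet-style MaxEnt


FEATURE_CLASS_COMBOS: tuple[tuple[str, ...], ...] = (
    ("L",), ("Q",), ("H",), ("L", "Q"), ("L", "H"), ("Q", "H"), ("L", "Q", "H"),
)
#: default per-class L1 penalty scale (hinge penalized more lightly, as in maxnet)
CLASS_PENALTY = {"L": 1.0, "Q": 1.0, "H": 0.5}


def _hinge_knots(bg_col: np.ndarray, n_knots: int) -> np.ndarray:
    qs = np.linspace(0.0, 1.0, n_knots + 2)[1:-1]
    return np.unique(np.quantile(bg_col, qs))


@dataclasses.dataclass
class _FeatureMap:
    """Expansion of raw variables into model features."""

    feature_classes: tuple[str, ...]
    variable_names: list[str]
    knots: list[np.ndarray]  # per-variable hinge knots
    var_min: np.ndarray
    var_max: np.ndarray
    mean: np.ndarray | None = None  # post-expansion standardization moments
    sd: np.ndarray | None = None
    penalty: np.ndarray | None = None

    def expand(self, X: np.ndarray) -> np.ndarray:
        cols = []
        if "L" in self.feature_classes:
            cols.append(X)
        if "Q" in self.feature_classes:
            cols.append(X**2)
        if "H" in self.feature_classes:
            for j in range(X.shape[1]):
                for k in self.knots[j]:
                    denom_f = max(self.var_max[j] - k, 1e-12)
                    denom_r = max(k - self.var_min[j], 1e-12)
                    cols.append(np.clip((X[:, j] - k) / denom_f, 0.0, 1.0)[:, None])
                    cols.append(np.clip((k - X[:, j]) / denom_r, 0.0, 1.0)[:, None])
        return np.hstack(cols)

    def transform(self, X: np.ndarray) -> np.ndarray:
        feats = self.expand(np.asarray(X, dtype=float))
        return (feats - self.mean) / self.sd / self.penalty


def build_feature_map(
    X_background: np.ndarray,
    feature_classes: tuple[str, ...],
    variable_names: list[str],
    n_hinge_knots: int = 8,
    reg_mult: float = 1.0,
) -> _FeatureMap:
    fc = tuple(c for c in ("L", "Q", "H") if c in feature_classes)
    if not fc:
        raise ValueError("feature_classes must be a nonempty subset of {L, Q, H}")
    Xb = np.asarray(X_background, dtype=float)
    knots = [
        _hinge_knots(Xb[:, j], n_hinge_knots) if "H" in fc else np.empty(0)
        for j in range(Xb.shape[1])
    ]
    fm = _FeatureMap(
        feature_classes=fc,
        variable_names=list(variable_names),
        knots=knots,
        var_min=Xb.min(axis=0),
        var_max=Xb.max(axis=0),
    )
    feats = fm.expand(Xb)
    fm.mean = feats.mean(axis=0)
    fm.sd = np.where(feats.std(axis=0) > 0, feats.std(axis=0), 1.0)
    # per-feature penalty scale, applied through feature scaling so a single
    # global L1 strength yields per-class penalties lambda_j = reg_mult * class
    pen = []
    nvar = Xb.shape[1]
    if "L" in fc:
        pen += [CLASS_PENALTY["L"]] * nvar
    if "Q" in fc:
        pen += [CLASS_PENALTY["Q"]] * nvar
    if "H" in fc:
        for j in range(nvar):
            pen += [CLASS_PENALTY["H"]] * (2 * len(knots[j]))
    fm.penalty = np.asarray(pen) * reg_mult
    return fm


@dataclasses.dataclass
class MaxnetModel(SuitabilityModel):
    """L1-penalized IWLR maxnet-style model with cloglog output."""

    feature_map: _FeatureMap
    coef: np.ndarray
    intercept: float
    log_z: float  # log partition over training background (raw normalization)
    entropy: float  # entropy of the raw distribution over training background
    feature_classes: tuple[str, ...] = ("L", "Q", "H")
    reg_mult: float = 1.0
    algorithm: str = "maxent"
    importance: dict[str, float] | None = None

    @property
    def variable_names(self) -> list[str]:
        return self.feature_map.variable_names

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return self.feature_map.transform(X) @ self.coef

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Complementary log-log suitability in [0, 1]."""
        raw = np.exp(self.linear_predictor(X) - self.log_z)
        return 1.0 - np.exp(-np.exp(self.entropy) * raw)

    def predict_logistic(self, X: np.ndarray) -> np.ndarray:
        return expit(self.intercept + self.linear_predictor(X))


def fit_maxent(
    X_presences: np.ndarray,
    X_background: np.ndarray,
    feature_classes: tuple[str, ...] = ("L", "Q", "H"),
    reg_mult: float = 1.0,
    variable_names: list[str] | None = None,
    bg_weight: float = 100.0,
    n_hinge_knots: int = 8,
    lambda0: float = 0.05,
) -> MaxnetModel:
    """Fit the maxnet-style model.

    The optimization target is the weighted logistic deviance (presences
    weight 1, background weight ``bg_weight``) normalized by the number of
    presences, plus an L1 penalty ``lambda0 * reg_mult * sum_j c_j |beta_j|``
    with per-class scale ``c_j`` (hinge features penalized at half the
    linear/quadratic rate). Hinge knots sit at empirical quantiles of the
    background. Prediction uses the complementary log-log transform of the
    raw (normalized-exponential) output.
    """
    Xp = np.atleast_2d(np.asarray(X_presences, dtype=float))
    Xb = np.atleast_2d(np.asarray(X_background, dtype=float))
    if Xp.shape[0] < 2:
        raise ValueError("need at least 2 presences")
    if reg_mult <= 0:
        raise ValueError("reg_mult must be positive")
    names = variable_names if variable_names is not None else [f"x{j}" for j in range(Xp.shape[1])]

    fm = build_feature_map(Xb, feature_classes, names, n_hinge_knots=n_hinge_knots, reg_mult=reg_mult)
    Fp = fm.transform(Xp)
    Fb = fm.transform(Xb)
    F = np.vstack([Fp, Fb])
    y = np.concatenate([np.ones(len(Fp)), np.zeros(len(Fb))])
    w = np.concatenate([np.ones(len(Fp)), np.full(len(Fb), bg_weight)])

    # sklearn objective: C * sum_i w_i * nll_i + ||beta||_1  (intercept free);
    # matching (1/n_pres) sum w nll + lambda0*|beta| needs C = 1/(n_pres*lambda0)
    clf = LogisticRegression(
        l1_ratio=1.0,
        C=1.0 / (len(Fp) * lambda0),
        solver="liblinear",
        max_iter=2000,
        tol=1e-8,
        random_state=0,
    )
    clf.fit(F, y, sample_weight=w)
    coef = clf.coef_.ravel()
    intercept = float(clf.intercept_[0])

    eta_bg = Fb @ coef
    log_z = float(np.log(np.sum(np.exp(eta_bg - eta_bg.max()))) + eta_bg.max())
    raw_bg = np.exp(eta_bg - log_z)
    with np.errstate(divide="ignore", invalid="ignore"):
        entropy = float(-np.sum(raw_bg * np.where(raw_bg > 0, np.log(raw_bg), 0.0)))

    return MaxnetModel(
        feature_map=fm,
        coef=coef,
        intercept=intercept,
        log_z=log_z,
        entropy=entropy,
        feature_classes=fm.feature_classes,
        reg_mult=reg_mult,
    )


def _cv_scores(fit_fn, Xp, Xb, pres_folds, bg_folds) -> list[dict[str, float]]:
    """Per-fold metric dicts: fit on 3 blocks, score on the held-out block."""
    out = []
    for k in np.unique(pres_folds):
        tr_p, te_p = pres_folds != k, pres_folds == k
        tr_b, te_b = bg_folds != k, bg_folds == k
        if te_p.sum() == 0 or te_b.sum() == 0:
            continue
        model = fit_fn(Xp[tr_p], Xb[tr_b])
        out.append(score_predictions(model.predict(Xp[te_p]), model.predict(Xb[te_b])))
    if not out:
        raise ValueError("no usable folds")
    return out


def evaluate_model_cv(fit_fn, Xp, Xb, pres_folds, bg_folds):
    """Cross-validated EvaluationReport for a fitting closure."""
    from rangeshift.evaluation import build_report

    return build_report(_cv_scores(fit_fn, Xp, Xb, pres_folds, bg_folds))


def tune_maxent(
    X_presences: np.ndarray,
    X_background: np.ndarray,
    pres_folds: np.ndarray,
    bg_folds: np.ndarray,
    feature_combos: tuple[tuple[str, ...], ...] = FEATURE_CLASS_COMBOS,
    reg_mults: np.ndarray | None = None,
    variable_names: list[str] | None = None,
    **fit_kwargs,
) -> tuple[tuple[str, ...], float, pd.DataFrame]:
    """Grid-search feature classes x regularization multiplier.

    Candidates are scored by mean cross-validated omission rate at the
    maxSSS threshold; ties break by higher mean TSS, then smaller
    multiplier. Returns (best feature classes, best multiplier, leaderboard).
    """
    if reg_mults is None:
        reg_mults = np.round(np.arange(1.0, 10.0 + 1e-9, 0.1), 1)
    rows = []
    for fc, rm in itertools.product(feature_combos, reg_mults):
        def fit_fn(Xp, Xb, fc=fc, rm=rm):
            return fit_maxent(Xp, Xb, feature_classes=fc, reg_mult=rm,
                              variable_names=variable_names, **fit_kwargs)

        folds = _cv_scores(fit_fn, X_presences, X_background, pres_folds, bg_folds)
        rows.append(
            {
                "feature_classes": "".join(fc),
                "reg_mult": float(rm),
                "mean_omission": float(np.mean([f["omission_rate"] for f in folds])),
                "mean_tss": float(np.mean([f["tss"] for f in folds])),
            }
        )
    board = pd.DataFrame(rows).sort_values(
        by=["mean_omission", "mean_tss", "reg_mult"],
        ascending=[True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    best = board.iloc[0]
    return tuple(best["feature_classes"]), float(best["reg_mult"]), board


# ---------------------------------------------------------------------------
# tree models


@dataclasses.dataclass
class TreeModel(SuitabilityModel):
    """sklearn tree ensemble wrapped as a suitability model."""

    estimator: object
    variable_names: list[str]
    variable_index: np.ndarray  # columns of the full matrix the model uses
    algorithm: str = "RF"
    importance: dict[str, float] | None = None
    hyperparams: dict | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict_proba(np.asarray(X)[:, self.variable_index])[:, 1]


DEFAULT_TREE_GRIDS = {
    "RF": [
        {"n_estimators": 300, "min_samples_leaf": 5, "max_features": "sqrt"},
        {"n_estimators": 300, "min_samples_leaf": 1, "max_features": "sqrt"},
        {"n_estimators": 300, "min_samples_leaf": 10, "max_features": 0.5},
    ],
    "BRT": [
        {"n_estimators": 150, "learning_rate": 0.1, "max_depth": 2},
        {"n_estimators": 150, "learning_rate": 0.1, "max_depth": 3},
        {"n_estimators": 300, "learning_rate": 0.05, "max_depth": 3},
    ],
}


def _make_estimator(algorithm: str, params: dict, seed: int):
    if algorithm == "RF":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if algorithm == "BRT":
        return GradientBoostingClassifier(random_state=seed, **params)
    raise ValueError(f"unknown tree algorithm {algorithm!r}")


def _fit_est(algorithm, params, Xp, Xb, seed):
    X = np.vstack([Xp, Xb])
    y = np.concatenate([np.ones(len(Xp)), np.zeros(len(Xb))])
    w = np.concatenate([np.ones(len(Xp)), np.full(len(Xb), len(Xp) / max(len(Xb), 1))])
    est = _make_estimator(algorithm, params, seed)
    est.fit(X, y, sample_weight=w)
    return est


def _cv_tss(algorithm, params, Xp, Xb, pres_folds, bg_folds, seed, nperm: int = 0):
    """Mean held-out TSS and (optionally) held-out permutation importance.

    Importance is measured on the withheld block so noise variables that an
    overfit tree memorizes in-sample still score near zero.
    """
    from rangeshift.evaluation import confusion_metrics

    vals = []
    imps = []
    for k in np.unique(pres_folds):
        est = _fit_est(algorithm, params, Xp[pres_folds != k], Xb[bg_folds != k], seed)
        Xte = np.vstack([Xp[pres_folds == k], Xb[bg_folds == k]])
        yte = np.concatenate(
            [np.ones(int((pres_folds == k).sum()), int), np.zeros(int((bg_folds == k).sum()), int)]
        )
        sc = est.predict_proba(Xte)[:, 1]
        t = threshold_maxSSS(yte, sc)
        vals.append(confusion_metrics(yte, (sc >= t).astype(int))["tss"])
        if nperm:
            imps.append(
                permutation_importance_scores(
                    lambda Z: est.predict_proba(Z)[:, 1], Xte, yte, nperm=nperm, seed=seed
                )
            )
    tss = float(np.mean(vals))
    if not nperm:
        return tss
    return tss, np.mean(imps, axis=0)


def permutation_importance_scores(
    predict_fn, X: np.ndarray, y: np.ndarray, nperm: int = 100, seed: int = 0
) -> np.ndarray:
    """Per-variable permutation importance, rescaled to sum to 100.

    Importance of variable j is the mean drop in AUC over ``nperm``
    reshuffles of column j (negative drops floor at 0 before rescaling).
    """
    from rangeshift.evaluation import rank_metrics

    rng = np.random.default_rng(seed)
    base = rank_metrics(y, predict_fn(X))["auc"]
    drops = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        for _ in range(nperm):
            Xs = X.copy()
            Xs[:, j] = rng.permutation(Xs[:, j])
            drops[j] += base - rank_metrics(y, predict_fn(Xs))["auc"]
    drops = np.maximum(drops / nperm, 0.0)
    total = drops.sum()
    if total == 0:
        return np.full(X.shape[1], 100.0 / X.shape[1])
    return drops / total * 100.0


def permutation_importance(model: SuitabilityModel, X_presences, X_background,
                           nperm: int = 100, seed: int = 0) -> dict[str, float]:
    """Importance (%) per variable of a fitted suitability model."""
    X = np.vstack([X_presences, X_background])
    y = np.concatenate([np.ones(len(X_presences), int), np.zeros(len(X_background), int)])
    vals = permutation_importance_scores(model.predict, X, y, nperm=nperm, seed=seed)
    return dict(zip(model.variable_names, (float(v) for v in vals)))


def fit_tree_model(
    algorithm: str,
    X_presences: np.ndarray,
    X_background: np.ndarray,
    pres_folds: np.ndarray,
    bg_folds: np.ndarray,
    variable_names: list[str] | None = None,
    nperm: int = 100,
    importance_threshold: float = 5.0,
    param_grid: list[dict] | None = None,
    seed: int = 0,
) -> TreeModel:
    """Fit RF or BRT with variable reduction and hyperparameter search.

    Loop: fit, compute permutation importance, and drop the weakest variable
    while its importance is below ``importance_threshold`` percent and the
    cross-validated TSS does not degrade; then pick the hyperparameter
    combination with the best mean test TSS.
    """
    if algorithm not in DEFAULT_TREE_GRIDS:
        raise ValueError(f"unknown tree algorithm {algorithm!r}; options: {list(DEFAULT_TREE_GRIDS)}")
    Xp = np.atleast_2d(np.asarray(X_presences, dtype=float))
    Xb = np.atleast_2d(np.asarray(X_background, dtype=float))
    names = list(variable_names) if variable_names is not None else [f"x{j}" for j in range(Xp.shape[1])]
    grid = param_grid if param_grid is not None else DEFAULT_TREE_GRIDS[algorithm]
    base_params = grid[0]

    active = np.arange(Xp.shape[1])
    if active.size < 1:
        raise ValueError("need at least one predictor")
    # tolerance absorbs fit-to-fit stochastic jitter in the test TSS
    tss_tol = 0.04
    cur_tss, imp = _cv_tss(
        algorithm, base_params, Xp[:, active], Xb[:, active], pres_folds, bg_folds, seed, nperm=nperm
    )
    while active.size > 1:
        weakest = int(np.argmin(imp))
        if imp[weakest] >= importance_threshold:
            break
        trial = np.delete(active, weakest)
        trial_tss, trial_imp = _cv_tss(
            algorithm, base_params, Xp[:, trial], Xb[:, trial], pres_folds, bg_folds, seed, nperm=nperm
        )
        if trial_tss >= cur_tss - tss_tol:
            logger.debug("%s: dropping %s (importance %.2f%%)", algorithm, names[active[weakest]], imp[weakest])
            active, cur_tss, imp = trial, trial_tss, trial_imp
        else:
            break

    best_params, best_tss = None, -np.inf
    for params in grid:
        tss = _cv_tss(algorithm, params, Xp[:, active], Xb[:, active], pres_folds, bg_folds, seed)
        if tss > best_tss:
            best_params, best_tss = params, tss

    est = _fit_est(algorithm, best_params, Xp[:, active], Xb[:, active], seed)
    model = TreeModel(
        estimator=est,
        variable_names=[names[j] for j in active],
        variable_index=active,
        algorithm=algorithm,
        hyperparams=dict(best_params),
    )
    if active.size == Xp.shape[1] and active.size == 1:
        warnings.warn("single-predictor model; no variable reduction possible", stacklevel=2)
    model.importance = permutation_importance(model, Xp, Xb, nperm=nperm, seed=seed)
    return model


def save_model(model: SuitabilityModel, path) -> None:
    """Versioned pickle artifact with a JSON metadata sidecar."""
    import json
    import pickle
    from pathlib import Path

    from rangeshift import __version__

    path = Path(path)
    with open(path, "wb") as fh:
        pickle.dump({"format_version": 1, "rangeshift": __version__, "model": model}, fh)
    sidecar = {
        "format_version": 1,
        "rangeshift": __version__,
        "algorithm": model.algorithm,
        "variable_names": list(model.variable_names),
        "importance": model.importance,
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_model(path) -> SuitabilityModel:
    import pickle

    with open(path, "rb") as fh:
        blob = pickle.load(fh)
    if blob.get("format_version") != 1:
        raise ValueError(f"unsupported model artifact version {blob.get('format_version')!r}")
    return blob["model"]


@dataclasses.dataclass
class BootstrapEnsembleModel(SuitabilityModel):
    """Bagged tree learner exposing prediction spread as uncertainty.

    Default stand-in for any member model that reports per-cell uncertainty:
    ``predict`` is the bootstrap mean, ``uncertainty`` the bootstrap
    standard deviation.
    """

    members: list[object]
    variable_names: list[str]
    algorithm: str = "bagged_trees"
    importance: dict[str, float] | None = None

    def _member_preds(self, X: np.ndarray) -> np.ndarray:
        return np.stack([m.predict_proba(X)[:, 1] for m in self.members])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._member_preds(np.asarray(X)).mean(axis=0)

    def uncertainty(self, X: np.ndarray) -> np.ndarray:
        return self._member_preds(np.asarray(X)).std(axis=0)


def fit_bootstrap_ensemble(
    X_presences: np.ndarray,
    X_background: np.ndarray,
    variable_names: list[str] | None = None,
    n_members: int = 15,
    base_params: dict | None = None,
    seed: int = 0,
) -> BootstrapEnsembleModel:
    """Bootstrap-bagged BRT ensemble with per-cell uncertainty."""
    Xp = np.atleast_2d(np.asarray(X_presences, dtype=float))
    Xb = np.atleast_2d(np.asarray(X_background, dtype=float))
    names = list(variable_names) if variable_names is not None else [f"x{j}" for j in range(Xp.shape[1])]
    params = base_params or {"n_estimators": 100, "learning_rate": 0.1, "max_depth": 2}
    rng = np.random.default_rng(seed)
    members = []
    for _ in range(n_members):
        ip = rng.integers(0, len(Xp), len(Xp))
        ib = rng.integers(0, len(Xb), len(Xb))
        members.append(_fit_est("BRT", params, Xp[ip], Xb[ib], int(rng.integers(2**31))))
    return BootstrapEnsembleModel(members=members, variable_names=names)
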