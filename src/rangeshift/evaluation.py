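"""Discrimination and calibration metrics, thresholds, and CV scoring.

Seven metrics are used throughout the pipeline: AUC, AUC-PR, TSS and
Sørensen's index (discrimination); Brier score, Cohen's kappa and the
Continuous Boyce Index (calibration). Thresholds come from maximizing
sensitivity + specificity (maxSSS) or Sørensen's index over observed score
values. Kappa and the confusion-table metrics of a continuous model are
taken at the maxSSS threshold.
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score


def _check_binary(obs: np.ndarray) -> np.ndarray:
    obs = np.asarray(obs)
    classes = np.unique(obs)
    if not np.isin(classes, (0, 1)).all():
        raise ValueError("observations must be 0/1")
    if classes.size < 2:
        raise ValueError(f"degenerate observations: only class {int(classes[0])} present")
    return obs.astype(int)


def confusion_metrics(obs_binary, pred_binary) -> dict[str, float]:
    """Closed-form 2x2-table metrics: sensitivity, specificity, TSS, Sørensen, kappa."""
    obs = _check_binary(obs_binary)
    pred = np.asarray(pred_binary).astype(int)
    if obs.shape != pred.shape:
        raise ValueError("obs and pred must have equal length")
    tp = int(((obs == 1) & (pred == 1)).sum())
    fn = int(((obs == 1) & (pred == 0)).sum())
    fp = int(((obs == 0) & (pred == 1)).sum())
    tn = int(((obs == 0) & (pred == 0)).sum())
    n = tp + fn + fp + tn
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    sorensen = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    po = (tp + tn) / n
    pe = ((tp + fn) * (tp + fp) + (tn + fp) * (tn + fn)) / n**2
    kappa = (po - pe) / (1.0 - pe) if pe < 1.0 else 0.0
    return {
        "sensitivity": sens,
        "specificity": spec,
        "tss": sens + spec - 1.0,
        "sorensen": sorensen,
        "kappa": kappa,
    }


def rank_metrics(obs_binary, scores) -> dict[str, float]:
    """AUC (Mann-Whitney with tie correction), AUC-PR (step PR integration), Brier."""
    obs = _check_binary(obs_binary)
    scores = np.asarray(scores, dtype=float)
    n1 = int(obs.sum())
    n0 = obs.size - n1
    ranks = stats.rankdata(scores)  # average ranks handle ties
    auc = (ranks[obs == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    auc_pr = float(average_precision_score(obs, scores))
    brier = float(np.mean((scores - obs) ** 2))
    return {"auc": float(auc), "auc_pr": auc_pr, "brier": brier}


def continuous_boyce(
    scores_at_presences,
    scores_at_background,
    n_windows: int = 101,
    window_frac: float = 0.02,
) -> float:
    """Continuous Boyce Index.

    Moving windows of width ``window_frac`` x the background score range are
    slid over ``n_windows`` centers; per window the predicted-to-expected
    ratio P/E = (fraction of presences in window)/(fraction of background in
    window) is computed (windows with zero expected fraction are skipped),
    and CBI is the Spearman correlation between window center and P/E.

    The default window width (0.02 of the range) is narrower than the
    common 0.1 convention: wide overlapping windows leave so few effective
    degrees of freedom that the null distribution of the index is badly
    dispersed; both knobs are exposed.
    """
    pres = np.asarray(scores_at_presences, dtype=float)
    bg = np.asarray(scores_at_background, dtype=float)
    if pres.size == 0 or bg.size == 0:
        raise ValueError("presence and background score sets must be nonempty")
    lo = min(pres.min(), bg.min())
    hi = max(pres.max(), bg.max())
    if hi == lo:
        raise ValueError("all scores identical; Boyce index undefined")
    width = window_frac * (hi - lo)
    centers = np.linspace(lo + width / 2.0, hi - width / 2.0, n_windows)
    pe, used_centers = [], []
    for c in centers:
        in_p = ((pres >= c - width / 2.0) & (pres <= c + width / 2.0)).mean()
        in_b = ((bg >= c - width / 2.0) & (bg <= c + width / 2.0)).mean()
        if in_b > 0:
            pe.append(in_p / in_b)
            used_centers.append(c)
    if len(pe) < 2:
        raise ValueError("all moving windows empty; cannot compute Boyce index")
    rho = stats.spearmanr(used_centers, pe).statistic
    return float(rho) if np.isfinite(rho) else 0.0


def _threshold_candidates(scores: np.ndarray) -> np.ndarray:
    uniq = np.unique(scores)
    return np.append(uniq, uniq[-1] + 1.0)


def _best_threshold(obs: np.ndarray, scores: np.ndarray, objective) -> float:
    """Lowest observed-score threshold maximizing ``objective`` of (obs, scores >= t)."""
    best_t, best_v = None, -np.inf
    for t in _threshold_candidates(scores):
        v = objective(obs, (scores >= t).astype(int))
        if v > best_v + 1e-12:
            best_t, best_v = t, v
    return float(best_t)


def threshold_maxSSS(obs_binary, scores) -> float:
    """Threshold maximizing sensitivity + specificity (ties -> lowest)."""
    obs = _check_binary(obs_binary)
    scores = np.asarray(scores, dtype=float)

    def sss(o, p):
        tp = ((o == 1) & (p == 1)).sum()
        fn = ((o == 1) & (p == 0)).sum()
        fp = ((o == 0) & (p == 1)).sum()
        tn = ((o == 0) & (p == 0)).sum()
        return tp / (tp + fn) + tn / (tn + fp)

    return _best_threshold(obs, scores, sss)


def threshold_maxSorensen(obs_binary, scores) -> float:
    """Threshold maximizing Sørensen's index (ties -> lowest)."""
    obs = _check_binary(obs_binary)
    scores = np.asarray(scores, dtype=float)

    def sor(o, p):
        tp = ((o == 1) & (p == 1)).sum()
        fn = ((o == 1) & (p == 0)).sum()
        fp = ((o == 0) & (p == 1)).sum()
        return 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0

    return _best_threshold(obs, scores, sor)


def omission_rate(obs_presences_scores, threshold: float) -> float:
    """Fraction of presences scoring strictly below ``threshold``."""
    scores = np.asarray(obs_presences_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("presence scores must be nonempty")
    return float((scores < threshold).mean())


# ---------------------------------------------------------------------------
# reports


@dataclasses.dataclass
class EvaluationReport:
    """The seven metrics, the two thresholds, and per-fold detail."""

    auc: float
    auc_pr: float
    tss: float
    sorensen: float
    kappa: float
    brier: float
    cbi: float
    thresholds: dict[str, float]
    per_fold: list[dict[str, float]] = dataclasses.field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    def per_fold_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_fold)


def score_predictions(pres_scores: np.ndarray, bg_scores: np.ndarray) -> dict[str, float]:
    """All seven metrics for one presence/background score split.

    Confusion-table metrics and kappa are evaluated at the maxSSS threshold.
    """
    obs = np.concatenate([np.ones(len(pres_scores), dtype=int), np.zeros(len(bg_scores), dtype=int)])
    scores = np.concatenate([pres_scores, bg_scores])
    t_sss = threshold_maxSSS(obs, scores)
    t_sor = threshold_maxSorensen(obs, scores)
    out = confusion_metrics(obs, (scores >= t_sss).astype(int))
    out.update(rank_metrics(obs, scores))
    try:
        out["cbi"] = continuous_boyce(pres_scores, bg_scores)
    except ValueError as exc:
        warnings.warn(f"CBI unavailable: {exc}", stacklevel=2)
        out["cbi"] = float("nan")
    out["threshold_maxSSS"] = t_sss
    out["threshold_maxSorensen"] = t_sor
    out["omission_rate"] = omission_rate(pres_scores, t_sss)
    return out


def build_report(per_fold: list[dict[str, float]]) -> EvaluationReport:
    """Mean-over-folds EvaluationReport from per-fold metric dicts."""
    if not per_fold:
        raise ValueError("need at least one fold")
    mean = {k: float(np.nanmean([f[k] for f in per_fold])) for k in per_fold[0]}
    return EvaluationReport(
        auc=mean["auc"],
        auc_pr=mean["auc_pr"],
        tss=mean["tss"],
        sorensen=mean["sorensen"],
        kappa=mean["kappa"],
        brier=mean["brier"],
        cbi=mean["cbi"],
        thresholds={
            "maxSSS": mean["threshold_maxSSS"],
            "maxSorensen": mean["threshold_maxSorensen"],
        },
        per_fold=per_fold,
    )
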