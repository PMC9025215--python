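"""Ensembles of gated member models, scenario projection, and masks.

Member models whose cross-validated TSS clears the gate (default 0.6) are
combined cell-wise by one of five methods — median, mean, TSS-weighted
mean, committee average of member binary maps, or the first principal
component of the member maps. Projections outside the training predictor
ranges are removed by a clamping mask; members exposing per-cell
uncertainty additionally mask the most uncertain cells.
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np

from rangeshift.evaluation import EvaluationReport
from rangeshift.predictors import PredictorStack

ENSEMBLE_METHODS = ("median", "mean", "weighted_mean", "committee_average", "pca")


@dataclasses.dataclass
class Member:
    """A gated ensemble member: fitted model + its evaluation."""

    model: object  # SuitabilityModel
    evaluation: EvaluationReport

    @property
    def tss(self) -> float:
        return self.evaluation.tss

    @property
    def maxsss_threshold(self) -> float:
        return self.evaluation.thresholds["maxSSS"]


@dataclasses.dataclass
class EnsembleSpec:
    method: str
    member_ids: list[int]
    weights: list[float] | None = None  # per-member TSS for weighted_mean
    tss_min: float = 0.6

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))


def gate_members(members: list[Member], tss_min: float = 0.6) -> list[Member]:
    """Members with TSS >= tss_min, order preserved (inclusive boundary)."""
    return [m for m in members if m.tss >= tss_min]


def combine(
    member_maps: list[np.ndarray],
    method: str,
    weights: list[float] | None = None,
    thresholds: list[float] | None = None,
) -> np.ndarray:
    """Cell-wise combination of co-registered member suitability maps.

    ``weights`` (member TSS values) are required for ``weighted_mean``,
    ``thresholds`` (per-member maxSSS) for ``committee_average``. NaN cells
    propagate. Output is in [0, 1].
    """
    if not member_maps:
        raise ValueError("cannot combine an empty member list")
    stack = np.stack([np.asarray(m, dtype=float) for m in member_maps])
    if method == "median":
        return np.median(stack, axis=0)
    if method == "mean":
        return stack.mean(axis=0)
    if method == "weighted_mean":
        if weights is None or len(weights) != len(member_maps):
            raise ValueError("weighted_mean needs one weight per member")
        w = np.asarray(weights, dtype=float)
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
        w = w / w.sum()
        return np.tensordot(w, stack, axes=1)
    if method == "committee_average":
        if thresholds is None or len(thresholds) != len(member_maps):
            raise ValueError("committee_average needs one threshold per member")
        binary = np.stack(
            [np.where(np.isnan(m), np.nan, (m >= t).astype(float)) for m, t in zip(stack, thresholds)]
        )
        return binary.mean(axis=0)
    if method == "pca":
        return _pca_combine(stack)
    raise ValueError(f"unknown ensemble method {method!r}; options: {ENSEMBLE_METHODS}")


def _pca_combine(stack: np.ndarray) -> np.ndarray:
    """First principal component of the cell x member matrix, sign-aligned
    with the member mean and min-max rescaled to [0, 1]."""
    flat = stack.reshape(stack.shape[0], -1).T  # (ncells, nmembers)
    valid = np.all(np.isfinite(flat), axis=1)
    out = np.full(flat.shape[0], np.nan)
    X = flat[valid]
    if X.shape[0] < 2 or X.shape[1] == 1:
        out[valid] = X[:, 0] if X.size else np.nan
        return out.reshape(stack.shape[1:])
    Xc = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    pc1 = Xc @ vt[0]
    mean_map = X.mean(axis=1)
    if np.corrcoef(pc1, mean_map)[0, 1] < 0:
        pc1 = -pc1
    rng_ = np.ptp(pc1)
    out[valid] = (pc1 - pc1.min()) / rng_ if rng_ > 0 else 0.5
    return out.reshape(stack.shape[1:])


def choose_best_ensemble(candidates: list[tuple[EnsembleSpec, EvaluationReport]]) -> tuple[EnsembleSpec, EvaluationReport]:
    """Maximize TSS; ties break by Sørensen, then by canonical method order."""
    if not candidates:
        raise ValueError("no ensemble candidates")
    order = {m: i for i, m in enumerate(ENSEMBLE_METHODS)}
    return max(
        candidates,
        key=lambda ce: (ce[1].tss, ce[1].sorensen, -order.get(ce[0].method, len(order))),
    )


def clamping_mask(projection_stack: PredictorStack, training_range: dict[str, tuple[float, float]],
                  names: list[str] | None = None) -> np.ndarray:
    """Per-cell count of predictors outside their training [min, max]."""
    names = names if names is not None else [n for n in projection_stack.names if n in training_range]
    count = np.zeros(projection_stack.grid.shape, dtype=int)
    for name in names:
        lo, hi = training_range[name]
        arr = projection_stack.layers[name]
        count += ((arr < lo) | (arr > hi)) & np.isfinite(arr)
    return count


def apply_clamping(suitability: np.ndarray, mask_counts: np.ndarray) -> np.ndarray:
    """NaN out cells where any predictor left its training range."""
    return np.where(mask_counts > 0, np.nan, suitability)


def uncertainty_mask(uncertainty_map: np.ndarray, quantile: float = 0.90) -> np.ndarray:
    """Boolean mask of cells at or above the given uncertainty quantile."""
    arr = np.asarray(uncertainty_map, dtype=float)
    vals = arr[np.isfinite(arr)]
    if vals.size == 0:
        raise ValueError("uncertainty map has no data cells")
    if np.ptp(vals) == 0:
        warnings.warn(
            "constant uncertainty map: every cell sits at the quantile and is masked",
            stacklevel=2,
        )
    cut = np.quantile(vals, quantile)
    return np.isfinite(arr) & (arr >= cut)


def apply_uncertainty(suitability: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return np.where(mask, np.nan, suitability)
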