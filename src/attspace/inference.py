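"""Bootstrap-subsampling inference and the polarization classification.

Uncertainty for every metric comes from a subsampling bootstrap: B random
subsamples of ``n_sub`` respondents are drawn WITHOUT replacement within a
group and the metric is recomputed on each.  Crucially the coordinates and
the pooled min-max scaling stay fixed from the full sample — only group
membership is resampled — so draws are comparable across groups and times.

Two bootstrap distributions are compared by the paired-difference p-value

    p = 2 * min(#(D <= 0) + 1, #(D >= 0) + 1) / (B + 1),  D_i = a_i - b_i,

capped at 1; the +1 smoothing keeps p >= 2/(B+1).  Point estimates (and the
percent changes built from them) always come from the FULL samples; the
bootstrap supplies intervals and p-values only.

The polarization diagnosis combines three contrasts (attitude position,
extremization, dispersion) between two groups or two time points:

* position difference not significant        -> "none"
* significant position difference, plus
    - extremization significantly higher AND dispersion significantly
      lower                                  -> "strong"
    - exactly one of those two signals       -> "moderate"
    - neither signal                         -> "weak"

Strong polarization means groups pulling apart while each becomes extreme
and internally homogeneous; weak means positions differ but the groups stay
diffuse and unaligned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import metrics as _m
from .metrics import ScaledCloud
from .survey_io import SurveyTable

__all__ = [
    "BootstrapResult",
    "Contrast",
    "bootstrap_metric",
    "compare_distributions",
    "distance_contrast",
    "percent_change",
    "classify_polarization",
    "DEFAULT_SEED",
]

DEFAULT_SEED = 20230716


@dataclass
class BootstrapResult:
    metric: str
    group: object
    point_estimate: float          # computed on the FULL sample
    draws: np.ndarray              # B resampled values
    ci: tuple                      # percentile 95% interval
    B: int
    n_sub: int
    seed: int
    axis: int | None = None
    other_group: object = None     # for pair metrics (distance_between)


@dataclass
class Contrast:
    metric: str
    group_a: object
    group_b: object
    delta: float                   # point_a - point_b
    percent_change: float          # 100 * delta / point_b (NaN if baseline 0)
    p_value: float
    direction: str                 # increase | decrease | none
    point_a: float = float("nan")
    point_b: float = float("nan")

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def _draw_indices(rng, n_group: int, n_sub: int, B: int,
                  with_replacement: bool) -> np.ndarray:
    if with_replacement:
        return rng.integers(0, n_group, size=(B, n_sub))
    if n_sub == n_group:
        # exhaustive: every without-replacement draw is the full group
        return np.tile(np.arange(n_group), (B, 1))
    keys = rng.random((B, n_group))
    return np.argsort(keys, axis=1)[:, :n_sub]


def bootstrap_metric(cloud: ScaledCloud, group, metric: str, n_sub: int,
                     B: int = 1000, seed: int = DEFAULT_SEED,
                     table: SurveyTable | None = None, axis: int = 0,
                     other_group=None, with_replacement: bool = False,
                     ci_level: float = 0.95) -> BootstrapResult:
    """Subsampling bootstrap distribution of one metric for one group.

    ``metric`` is one of position, extremization, dispersion, richness,
    top_index, originality, distance_between, entities, evenness.
    ``axis`` applies to position; ``other_group`` to distance_between;
    ``table`` to entities.  Scaling is never recomputed: the subsample
    lives in the full-sample cloud.
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    m = cloud.mask(group)
    idx_group = np.flatnonzero(m)
    n_group = len(idx_group)
    if n_sub > n_group:
        raise ValueError(f"n_sub={n_sub} exceeds group size {n_group}")
    rng = np.random.default_rng(seed)
    draws_idx = _draw_indices(rng, n_group, n_sub, B, with_replacement)

    X = cloud.coordinates[idx_group]
    w = cloud.weights[idx_group]
    norm = cloud.normalizer

    if metric == "position":
        point = _m.position(cloud, group, axis)
        vals = X[draws_idx, axis]                          # B x n_sub
        ws = w[draws_idx]
        draws = (vals * ws).sum(axis=1) / ws.sum(axis=1)
    elif metric == "extremization":
        point = _m.extremization(cloud, group)
        c = cloud.pooled_centroid()                        # fixed, full pooled sample
        dist = np.linalg.norm(X - c, axis=1)
        ds = dist[draws_idx]
        ws = w[draws_idx]
        draws = (ds * ws).sum(axis=1) / ws.sum(axis=1) / norm
    elif metric == "dispersion":
        point = _m.dispersion(cloud, group)
        pts = X[draws_idx]                                 # B x n_sub x d
        ws = w[draws_idx]
        wsum = ws.sum(axis=1, keepdims=True)
        cent = (pts * ws[..., None]).sum(axis=1) / wsum    # B x d
        dist = np.linalg.norm(pts - cent[:, None, :], axis=2)
        draws = (dist * ws).sum(axis=1) / wsum[:, 0] / norm
    elif metric == "distance_between":
        if other_group is None:
            raise ValueError("distance_between needs other_group")
        point = _m.distance_between(cloud, group, other_group)
        idx_b = np.flatnonzero(cloud.mask(other_group))
        if n_sub > len(idx_b):
            raise ValueError(f"n_sub={n_sub} exceeds group size {len(idx_b)}")
        Xb = cloud.coordinates[idx_b]
        wb = cloud.weights[idx_b]
        idx2 = _draw_indices(rng, len(idx_b), n_sub, B, with_replacement)
        wa = w[draws_idx]
        ca = (X[draws_idx] * wa[..., None]).sum(axis=1) / wa.sum(axis=1, keepdims=True)
        wbs = wb[idx2]
        cb = (Xb[idx2] * wbs[..., None]).sum(axis=1) / wbs.sum(axis=1, keepdims=True)
        draws = np.linalg.norm(ca - cb, axis=1) / norm
    else:
        # generic path: rebuild a subsample view and call the metric
        fn = {
            "richness": _m.richness, "top_index": _m.top_index,
            "originality": _m.originality, "evenness": _m.evenness,
        }.get(metric)
        if fn is None and metric != "entities":
            raise ValueError(f"unknown metric {metric!r}")
        if metric == "entities":
            if table is None:
                raise ValueError("entities needs the raw survey table")
            point = float(_m.entities(table, group)[0])
        else:
            point = fn(cloud, group)
        draws = np.empty(B)
        for b in range(B):
            sel = np.zeros(cloud.n, dtype=bool)
            sel[idx_group[draws_idx[b]]] = True
            sub = ScaledCloud(
                coordinates=cloud.coordinates[sel | ~m],
                groups=cloud.groups[sel | ~m],
                weights=cloud.weights[sel | ~m],
                axis_min=cloud.axis_min, axis_max=cloud.axis_max,
                normalizer=cloud.normalizer,
            )
            if metric == "entities":
                draws[b] = float(
                    len(table.responses.loc[table.groups.index[sel],
                        [it.item_id for it in table.items if it.kind == "ordinal"]]
                        .drop_duplicates()))
            else:
                draws[b] = fn(sub, group)
        point = float(point)

    alpha = 1.0 - ci_level
    lo, hi = np.quantile(draws, [alpha / 2, 1 - alpha / 2])
    return BootstrapResult(metric=metric, group=group, point_estimate=float(point),
                           draws=np.asarray(draws, dtype=float), ci=(float(lo), float(hi)),
                           B=B, n_sub=n_sub, seed=seed,
                           axis=axis if metric == "position" else None,
                           other_group=other_group)


def compare_distributions(a: BootstrapResult, b: BootstrapResult) -> Contrast:
    """Paired-difference contrast of two bootstrap distributions.

    Both results must share the metric and B.  The p-value is
    exchange-symmetric and bounded below by 2/(B+1); delta and percent
    change use the full-sample point estimates.
    """
    if a.metric != b.metric:
        raise ValueError(f"metric mismatch: {a.metric!r} vs {b.metric!r}")
    if a.B != b.B:
        raise ValueError(f"iteration mismatch: B={a.B} vs B={b.B}")
    D = a.draws - b.draws
    p = 2.0 * min((D <= 0).sum() + 1, (D >= 0).sum() + 1) / (a.B + 1)
    p = float(min(p, 1.0))
    delta = a.point_estimate - b.point_estimate
    pc = percent_change(a.point_estimate, b.point_estimate) \
        if b.point_estimate != 0 else float("nan")
    direction = "increase" if delta > 0 else ("decrease" if delta < 0 else "none")
    return Contrast(metric=a.metric, group_a=a.group, group_b=b.group,
                    delta=float(delta), percent_change=pc, p_value=p,
                    direction=direction, point_a=a.point_estimate,
                    point_b=b.point_estimate)


def distance_contrast(cloud: ScaledCloud, group_a, group_b, n_sub: int,
                      B: int = 1000, seed: int = DEFAULT_SEED,
                      with_replacement: bool = False) -> Contrast:
    """Test whether two group centroids coincide, via their distance.

    Each bootstrap iteration subsamples both groups and records the vector
    difference of their weighted centroids.  Per axis, the two-sided
    straddle-zero p-value (same +1-smoothed formula as
    :func:`compare_distributions`) asks whether the difference
    distribution crosses 0; the axis p-values are Bonferroni-combined.
    ``delta`` is the full-sample centroid distance on the 0-1 scale.
    """
    rng = np.random.default_rng(seed)
    out_diffs = None
    cents = {}
    for g in (group_a, group_b):
        idx = np.flatnonzero(cloud.mask(g))
        if n_sub > len(idx):
            raise ValueError(f"n_sub={n_sub} exceeds group size {len(idx)}")
        di = _draw_indices(rng, len(idx), n_sub, B, with_replacement)
        pts = cloud.coordinates[idx][di]
        ws = cloud.weights[idx][di]
        cents[g] = (pts * ws[..., None]).sum(axis=1) / ws.sum(axis=1, keepdims=True)
    diffs = cents[group_a] - cents[group_b]            # B x d
    le = (diffs <= 0).sum(axis=0) + 1
    ge = (diffs >= 0).sum(axis=0) + 1
    p_axis = np.minimum(2.0 * np.minimum(le, ge) / (B + 1), 1.0)
    p = float(min(1.0, cloud.d * p_axis.min()))
    dist = _m.distance_between(cloud, group_a, group_b)
    return Contrast(metric="distance_between", group_a=group_a, group_b=group_b,
                    delta=float(dist), percent_change=float("nan"), p_value=p,
                    direction="increase" if dist > 0 else "none",
                    point_a=float(dist), point_b=0.0)


def percent_change(current: float, baseline: float) -> float:
    """100 * (current - baseline) / baseline."""
    if baseline == 0:
        raise ZeroDivisionError("baseline is 0; percent change undefined")
    return 100.0 * (current - baseline) / baseline


def classify_polarization(position_contrast: Contrast,
                          extremization_contrast: Contrast,
                          dispersion_contrast: Contrast,
                          alpha: float = 0.05) -> str:
    """Diagnose polarization from three contrasts on the same pair.

    Returns "none", "weak", "moderate" or "strong" (see module docstring).
    All three contrasts must address the same (group_a, group_b) pair.
    """
    pair = (position_contrast.group_a, position_contrast.group_b)
    for c in (extremization_contrast, dispersion_contrast):
        if (c.group_a, c.group_b) != pair:
            raise ValueError("contrasts address different group pairs")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if position_contrast.p_value >= alpha:
        return "none"
    signals = 0
    if extremization_contrast.p_value < alpha and extremization_contrast.delta > 0:
        signals += 1
    if dispersion_contrast.p_value < alpha and dispersion_contrast.delta < 0:
        signals += 1
    return {2: "strong", 1: "moderate", 0: "weak"}[signals]
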