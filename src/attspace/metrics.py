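"""Distance-based attitude-diversity metrics on the scaled attitudinal space.

The coordinates are first min-max scaled per axis over the POOLED sample so
every axis spans [0, 1]; every distance-valued metric is then divided by
sqrt(d), the diagonal of the unit hypercube, so all of them live on a common
0-1 scale and are directly comparable across groups and surveys.

Seven group-level metrics, all borrowed from multidimensional trait-space
ecology:

======================  =====================================================
position                weighted mean coordinate of a group on one axis
extremization           mean distance of members to the POOLED centroid
dispersion              mean distance of members to their OWN group centroid
richness                group convex-hull volume / pooled convex-hull volume
top_index               summed areas of successively peeled hulls (d=2)
originality             mean nearest-neighbour distance within the group
distance_between        distance between two group centroids
entities                count of distinct raw response vectors (vs possible)
evenness                regularity of minimum-spanning-tree branch lengths
======================  =====================================================

Respondent weights enter centroids and metric means (community-weighted
means); the occupancy-type metrics (hull, TOP, nearest neighbour, MST,
entities) ignore weights.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import cdist, pdist, squareform

from .space_builder import AttitudinalSpace
from .survey_io import SurveyTable

__all__ = [
    "ScaledCloud",
    "GroupMetrics",
    "scale_space",
    "position",
    "extremization",
    "dispersion",
    "richness",
    "top_index",
    "originality",
    "distance_between",
    "entities",
    "evenness",
    "compute_all",
]


@dataclass
class ScaledCloud:
    """Min-max scaled respondent coordinates with group labels and weights.

    ``coordinates`` lie in the unit hypercube; ``axis_min``/``axis_max``
    record the pooled per-axis ranges used for scaling; ``normalizer`` is
    the constant every distance is divided by (sqrt(d) by default, or the
    maximum observed pooled distance when ``normalize_by="observed"``).
    """

    coordinates: np.ndarray          # n x d in [0, 1]
    groups: np.ndarray               # n labels
    weights: np.ndarray              # n nonnegative reals
    axis_min: np.ndarray
    axis_max: np.ndarray
    normalizer: float
    respondent_ids: np.ndarray = None

    def __post_init__(self):
        if self.respondent_ids is None:
            self.respondent_ids = np.arange(len(self.coordinates))

    @property
    def d(self) -> int:
        return self.coordinates.shape[1]

    @property
    def n(self) -> int:
        return self.coordinates.shape[0]

    def group_labels(self) -> list:
        return list(pd.unique(pd.Series(self.groups)))

    def mask(self, group) -> np.ndarray:
        m = self.groups == group
        if not m.any():
            raise KeyError(f"unknown group {group!r}")
        return m

    def pooled_centroid(self) -> np.ndarray:
        w = self.weights / self.weights.sum()
        return w @ self.coordinates


def scale_space(space, weights=None, normalize_by: str = "sqrt_d") -> ScaledCloud:
    """Min-max scale an AttitudinalSpace (or raw coordinates) to [0, 1] axes.

    Scaling uses the pooled sample so groups stay comparable.  A constant
    axis is an error: it carries no information and cannot be scaled.

    ``normalize_by``: "sqrt_d" (unit-hypercube diagonal, default) or
    "observed" (maximum observed pooled pairwise distance).
    """
    if isinstance(space, AttitudinalSpace):
        coords = np.asarray(space.scores, dtype=float)
        groups = np.asarray(space.groups)
        w = np.asarray(space.weights, dtype=float) if weights is None else np.asarray(weights, dtype=float)
        rids = np.asarray(space.respondent_ids)
    else:
        coords = np.asarray(space, dtype=float)
        groups = np.zeros(len(coords), dtype=object)
        w = np.ones(len(coords)) if weights is None else np.asarray(weights, dtype=float)
        rids = None
    if coords.shape[0] < 2:
        raise ValueError("need at least 2 respondents to scale a space")
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    if np.any(hi - lo == 0):
        bad = int(np.argmax(hi - lo == 0))
        raise ValueError(f"axis {bad + 1} is constant and cannot be scaled")
    scaled = (coords - lo) / (hi - lo)
    if normalize_by == "sqrt_d":
        norm = math.sqrt(coords.shape[1])
    elif normalize_by == "observed":
        norm = float(pdist(scaled).max())
        if norm == 0:
            raise ValueError("all respondents coincide; observed normalizer is 0")
    else:
        raise ValueError(f"unknown normalize_by {normalize_by!r}")
    return ScaledCloud(coordinates=scaled, groups=groups, weights=w,
                       axis_min=lo, axis_max=hi, normalizer=norm,
                       respondent_ids=rids)


def _wmean(values: np.ndarray, weights: np.ndarray) -> float:
    return float(np.average(values, weights=weights))


def _wcentroid(points: np.ndarray, weights: np.ndarray) -> np.ndarray:
    return np.average(points, axis=0, weights=weights)


# ---------------------------------------------------------------------------
# the metrics


def position(cloud: ScaledCloud, group, axis: int) -> float:
    """Weighted mean coordinate of the group on one axis (0-based index)."""
    m = cloud.mask(group)
    return _wmean(cloud.coordinates[m, axis], cloud.weights[m])


def extremization(cloud: ScaledCloud, group) -> float:
    """Mean distance of group members to the centroid of ALL respondents.

    The pooled centroid is weighted over every group; the member distances
    are averaged with the group's weights and divided by the normalizer.
    High values mean the group sits far from the population's centre of
    gravity on several axes at once (issue alignment).
    """
    m = cloud.mask(group)
    c = cloud.pooled_centroid()
    dists = np.linalg.norm(cloud.coordinates[m] - c, axis=1)
    return _wmean(dists, cloud.weights[m]) / cloud.normalizer


def dispersion(cloud: ScaledCloud, group) -> float:
    """Mean distance of group members to their OWN group centroid.

    The within-group analogue of extremization; low values mean a
    homogeneous group.  A singleton group has dispersion 0.
    """
    m = cloud.mask(group)
    pts = cloud.coordinates[m]
    if m.sum() == 1:
        return 0.0
    c = _wcentroid(pts, cloud.weights[m])
    dists = np.linalg.norm(pts - c, axis=1)
    return _wmean(dists, cloud.weights[m]) / cloud.normalizer


def _hull_volume(points: np.ndarray) -> float | None:
    """Convex-hull volume, or None when degenerate (too few / collinear)."""
    if points.shape[0] < points.shape[1] + 1:
        return None
    try:
        return float(ConvexHull(points).volume)
    except QhullError:
        return None


def richness(cloud: ScaledCloud, group) -> float:
    """Group convex-hull volume as a fraction of the pooled hull volume.

    Undefined (NaN, with a warning) when the group has fewer than d+1
    points or they are degenerate; an overlap-style occupancy measure in
    [0, 1].  Errors if the POOLED hull itself is degenerate.
    """
    pooled = _hull_volume(cloud.coordinates)
    if pooled is None or pooled == 0:
        raise ValueError("pooled convex hull is degenerate")
    m = cloud.mask(group)
    vol = _hull_volume(cloud.coordinates[m])
    if vol is None:
        warnings.warn(f"group {group!r}: hull undefined (size or collinearity)",
                      stacklevel=2)
        return float("nan")
    return vol / pooled


def top_index(cloud: ScaledCloud, group) -> float:
    """Sum of areas of successively peeled convex hulls (d = 2 only).

    Peel: take the hull, add its area, remove its vertices, repeat until
    fewer than 3 points remain or the rest are collinear.  More robust to
    sample size than a single hull.  Fewer than 3 points gives 0 with a
    warning.
    """
    if cloud.d != 2:
        raise ValueError("TOP index is defined for 2-dimensional spaces only")
    pts = cloud.coordinates[cloud.mask(group)]
    if len(pts) < 3:
        warnings.warn(f"group {group!r}: fewer than 3 points, TOP = 0",
                      stacklevel=2)
        return 0.0
    total = 0.0
    while len(pts) >= 3:
        try:
            hull = ConvexHull(pts)
        except QhullError:       # remaining points collinear
            break
        total += float(hull.volume)   # 2-D "volume" is the area
        pts = np.delete(pts, hull.vertices, axis=0)
    return total


def originality(cloud: ScaledCloud, group) -> float:
    """Mean distance of each member to its nearest OTHER member (same group).

    Measures the uniqueness of individual attitudes; collapses to 0 when
    every point has an exact duplicate.  Errors on singleton groups.
    """
    pts = cloud.coordinates[cloud.mask(group)]
    if len(pts) < 2:
        raise ValueError(f"group {group!r} has fewer than 2 members")
    D = squareform(pdist(pts))
    np.fill_diagonal(D, np.inf)
    return float(D.min(axis=1).mean()) / cloud.normalizer


def distance_between(cloud: ScaledCloud, group_a, group_b) -> float:
    """Distance between two weighted group centroids, on the 0-1 scale."""
    ca = _wcentroid(cloud.coordinates[cloud.mask(group_a)],
                    cloud.weights[cloud.mask(group_a)])
    cb = _wcentroid(cloud.coordinates[cloud.mask(group_b)],
                    cloud.weights[cloud.mask(group_b)])
    return float(np.linalg.norm(ca - cb)) / cloud.normalizer


def entities(table: SurveyTable, group) -> tuple[int, int]:
    """Distinct raw response vectors in a group, and the theoretical maximum.

    Computed on ordinal item codes only; continuous items are excluded from
    both the combination key and the level-count product (a warning notes
    the exclusion).  The maximum is the product of n_levels over ordinal
    items.
    """
    m = table.groups == group
    if not m.any():
        raise KeyError(f"unknown group {group!r}")
    ordinal = [it for it in table.items if it.kind == "ordinal"]
    if len(ordinal) < len(table.items):
        warnings.warn("continuous/categorical items excluded from entity key",
                      stacklevel=2)
    if not ordinal:
        raise ValueError("no ordinal items: entities undefined")
    sub = table.responses.loc[m, [it.item_id for it in ordinal]]
    count = int(len(sub.drop_duplicates()))
    max_possible = int(np.prod([it.n_levels for it in ordinal]))
    return count, max_possible


def _mst_edges(points: np.ndarray) -> np.ndarray:
    """Branch lengths of the Euclidean minimum spanning tree.

    Ties between equal-length edges break deterministically toward the
    lexicographically first (i, j) pair, via an infinitesimal index-ordered
    perturbation of the dense distance matrix.
    """
    n = len(points)
    D = squareform(pdist(points))
    iu = np.triu_indices(n, k=1)
    rank = np.arange(len(iu[0]), dtype=float)
    eps = np.zeros_like(D)
    eps[iu] = rank
    eps += eps.T
    span = minimum_spanning_tree(D + eps * 1e-12).tocoo()
    return D[span.row, span.col]


def evenness(cloud: ScaledCloud, group) -> float:
    """Regularity of the group's minimum-spanning-tree branch lengths.

    The S-1 branches of the MST over the group's S points each get a share
    of total branch length; shares are truncated at the equal share
    1/(S-1), summed, and rescaled to [0, 1]:

        EVE = (sum_b min(share_b, 1/(S-1)) - 1/(S-1)) / (1 - 1/(S-1))

    1 means perfectly regular spacing.  Needs S >= 3; an all-coincident
    group (zero-length MST) is 1 by convention, with a warning.
    """
    pts = cloud.coordinates[cloud.mask(group)]
    S = len(pts)
    if S < 3:
        raise ValueError(f"group {group!r}: evenness needs at least 3 members")
    lengths = _mst_edges(pts)
    total = lengths.sum()
    if total == 0:
        warnings.warn(f"group {group!r}: zero-length spanning tree, evenness 1",
                      stacklevel=2)
        return 1.0
    share = lengths / total
    eq = 1.0 / (S - 1)
    return float((np.minimum(share, eq).sum() - eq) / (1.0 - eq))


# ---------------------------------------------------------------------------
# bundle


@dataclass
class GroupMetrics:
    """All group-level metrics for one social group; NaN marks undefined."""

    group: object
    n: int
    position: np.ndarray                  # d axis means
    extremization: float
    dispersion: float
    richness: float                       # NaN when undefined
    top_index: float                      # NaN when d != 2
    originality: float                    # NaN for singleton groups
    entities: int
    entities_max: int
    evenness: float                       # NaN when n < 3
    flags: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {"group": self.group, "n": self.n}
        for k, v in zip(range(len(self.position)), self.position):
            out[f"position_axis_{k + 1}"] = v
        out.update(
            extremization=self.extremization, dispersion=self.dispersion,
            richness=self.richness, top_index=self.top_index,
            originality=self.originality, entities=self.entities,
            entities_max=self.entities_max, evenness=self.evenness,
        )
        return out


def compute_all(cloud: ScaledCloud, table: SurveyTable | None = None) -> list:
    """One GroupMetrics per group; undefined metrics become NaN and a flag.

    ``table`` supplies the raw codes for the entities count; when omitted,
    entities are reported as -1 ("not computed").
    """
    out = []
    for g in cloud.group_labels():
        m = cloud.mask(g)
        flags = {}
        pos = np.array([position(cloud, g, k) for k in range(cloud.d)])
        ext = extremization(cloud, g)
        disp = dispersion(cloud, g)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                rich = richness(cloud, g)
            except ValueError:
                rich, flags["richness"] = float("nan"), "pooled hull degenerate"
            if np.isnan(rich) and "richness" not in flags:
                flags["richness"] = "undefined (group size or collinearity)"
            top = top_index(cloud, g) if cloud.d == 2 else float("nan")
            if cloud.d != 2:
                flags["top_index"] = "defined for d=2 only"
            try:
                orig = originality(cloud, g)
            except ValueError:
                orig, flags["originality"] = float("nan"), "singleton group"
            try:
                eve = evenness(cloud, g)
            except ValueError:
                eve, flags["evenness"] = float("nan"), "needs >= 3 members"
            if table is not None:
                ent, ent_max = entities(table, g)
            else:
                ent, ent_max = -1, -1
                flags["entities"] = "no raw table supplied"
        out.append(GroupMetrics(
            group=g, n=int(m.sum()), position=pos, extremization=ext,
            dispersion=disp, richness=rich, top_index=top, originality=orig,
            entities=ent, entities_max=ent_max, evenness=eve, flags=flags,
        ))
    return out


def metrics_frame(metric_list) -> pd.DataFrame:
    """Tidy one-row-per-group DataFrame of a compute_all result."""
    return pd.DataFrame([gm.to_dict() for gm in metric_list]).set_index("group")
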