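"""Model/Results front end tying the pipeline together.

``AttitudinalSpaceModel`` holds the validated survey and the construction
choices; ``fit()`` runs filter -> impute -> dimensionality -> (rotated) PCA
or Gower/PCoA -> pooled min-max scaling and returns an
``AttitudinalSpaceResults`` carrying the space, the scaled cloud, the
group-level diversity metrics, bootstrap machinery and the polarization
classifier.  The functional modules (:mod:`survey_io`,
:mod:`space_builder`, :mod:`metrics`, :mod:`inference`) do all the work;
this layer only sequences them and presents the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import inference, metrics as _metrics, space_builder, survey_io
from .inference import DEFAULT_SEED

__all__ = ["AttitudinalSpaceModel", "AttitudinalSpaceResults", "ClassificationReport"]


@dataclass
class ClassificationReport:
    """Polarization diagnosis for one (group_a vs group_b) contrast."""

    group_a: object
    group_b: object
    label: str                      # none | weak | moderate | strong
    position: inference.Contrast    # most significant axis
    position_axis: int
    extremization: inference.Contrast
    dispersion: inference.Contrast
    distance: inference.Contrast
    alpha: float

    def to_dict(self) -> dict:
        def c(x):
            return {"delta": x.delta, "percent_change": x.percent_change,
                    "p_value": x.p_value, "direction": x.direction,
                    "point_a": x.point_a, "point_b": x.point_b}
        return {"group_a": str(self.group_a), "group_b": str(self.group_b),
                "label": self.label, "alpha": self.alpha,
                "position_axis": self.position_axis + 1,
                "position": c(self.position),
                "extremization": c(self.extremization),
                "dispersion": c(self.dispersion),
                "distance_between": c(self.distance)}


class AttitudinalSpaceModel:
    """Attitudinal-space construction for a respondent-by-item survey.

    Parameters
    ----------
    table : SurveyTable
        Validated survey (see :func:`attspace.survey_io.read_survey`).
    method : {"pca", "gower"}
        "pca": z-scored item codes, rotated principal components (requires
        complete data after imputation).  "gower": Gower dissimilarity +
        principal coordinates; tolerates missing cells and categoricals.
    rotation : {"none", "varimax", "promax", "auto"}
        PCA route only; "auto" keeps promax when |interfactor r| >= 0.3.
    d : int, optional
        Number of axes; default: eigenvalue-greater-than-1 rule on the
        polychoric/polyserial correlation matrix.
    max_missing_frac : float
        Respondents with a larger missing fraction are dropped before
        anything else (default 0.10, i.e. strictly more than 10% missing).
    """

    def __init__(self, table, method: str = "pca", rotation: str = "auto",
                 d: int | None = None, max_missing_frac: float = 0.10,
                 normalize_by: str = "sqrt_d", promax_power: int = 4):
        if method not in ("pca", "gower"):
            raise ValueError(f"unknown method {method!r}")
        self.table = table
        self.method = method
        self.rotation = rotation
        self.d = d
        self.max_missing_frac = max_missing_frac
        self.normalize_by = normalize_by
        self.promax_power = promax_power

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, items, group_column: str = "group",
                       weight_column: str | None = None, **kwargs):
        """Build the model straight from an in-memory DataFrame."""
        responses = df[[it.item_id for it in items]].astype(float)
        groups = df[group_column].astype(str).rename("group")
        weights = (pd.to_numeric(df[weight_column]).rename("weight")
                   if weight_column else None)
        table = survey_io.SurveyTable(responses=responses, groups=groups,
                                      items=list(items), weights=weights)
        return cls(table, **kwargs)

    @classmethod
    def from_csv(cls, path, items, group_column: str = "group",
                 weight_column: str | None = None, **kwargs):
        table = survey_io.read_survey(path, items, group_column, weight_column)
        return cls(table, **kwargs)

    def fit(self) -> "AttitudinalSpaceResults":
        """Run the construction pipeline and return the fitted results."""
        table = survey_io.filter_missing(self.table, self.max_missing_frac)
        if self.method == "pca":
            table = survey_io.impute_missing(table)
            space = space_builder.build_space(
                table, rotation=self.rotation, d=self.d,
                promax_power=self.promax_power)
        else:
            space = space_builder.build_space_gower(
                table, d=self.d if self.d is not None else 2)
        cloud = _metrics.scale_space(space, normalize_by=self.normalize_by)
        return AttitudinalSpaceResults(self, table, space, cloud)


class AttitudinalSpaceResults:
    """Fitted attitudinal space: coordinates, metrics, inference, summary."""

    def __init__(self, model: AttitudinalSpaceModel, table, space, cloud):
        self.model = model
        self.table = table
        self.space = space
        self.cloud = cloud
        self._metrics = None

    # -- estimates -----------------------------------------------------------
    @property
    def scores(self) -> pd.DataFrame:
        return self.space.scores_frame()

    @property
    def loadings(self):
        return self.space.loadings

    @property
    def variance_explained(self) -> np.ndarray:
        return self.space.variance_explained

    def group_metrics(self) -> pd.DataFrame:
        """Tidy per-group table of the seven diversity metrics (cached)."""
        if self._metrics is None:
            self._metrics = _metrics.metrics_frame(
                _metrics.compute_all(self.cloud, self.table))
        return self._metrics

    # -- inference -----------------------------------------------------------
    def bootstrap(self, metric: str, group, n_sub: int | None = None,
                  B: int = 1000, seed: int = DEFAULT_SEED, **kwargs):
        """Subsampling-bootstrap distribution of one metric for one group."""
        if n_sub is None:
            n_sub = int(np.sum(self.cloud.groups == group))
        return inference.bootstrap_metric(self.cloud, group, metric, n_sub,
                                          B=B, seed=seed, table=self.table,
                                          **kwargs)

    def contrast(self, metric: str, group_a, group_b,
                 n_sub: int | None = None, B: int = 1000,
                 seed: int = DEFAULT_SEED, **kwargs) -> inference.Contrast:
        """Bootstrap contrast of one metric between two groups/times.

        ``n_sub`` defaults to half the smaller group: half-sampling
        without replacement matches the sampling variance of the
        full-sample estimator, which keeps the paired-difference p-value
        approximately calibrated.
        """
        na = int(np.sum(self.cloud.groups == group_a))
        nb = int(np.sum(self.cloud.groups == group_b))
        if n_sub is None:
            n_sub = max(2, min(na, nb) // 2)
        if metric == "distance_between":
            return inference.distance_contrast(self.cloud, group_a, group_b,
                                               n_sub=min(n_sub, na, nb), B=B,
                                               seed=seed)
        a = self.bootstrap(metric, group_a, n_sub=min(n_sub, na), B=B,
                           seed=seed, **kwargs)
        b = self.bootstrap(metric, group_b, n_sub=min(n_sub, nb), B=B,
                           seed=seed + 1, **kwargs)
        return inference.compare_distributions(a, b)

    def classify(self, group_a, group_b, n_sub: int | None = None,
                 B: int = 1000, seed: int = DEFAULT_SEED,
                 alpha: float = 0.05) -> ClassificationReport:
        """Full polarization diagnosis of group_a vs group_b.

        Position is tested on every axis; the most significant axis is
        reported, with its p-value Bonferroni-corrected for the d axes
        searched so the "none" verdict keeps its nominal error rate.
        """
        import dataclasses

        pos = [self.contrast("position", group_a, group_b, n_sub=n_sub, B=B,
                             seed=seed + 10 * k, axis=k)
               for k in range(self.cloud.d)]
        best = int(np.argmin([c.p_value for c in pos]))
        pos[best] = dataclasses.replace(
            pos[best], p_value=min(1.0, self.cloud.d * pos[best].p_value))
        ext = self.contrast("extremization", group_a, group_b, n_sub=n_sub,
                            B=B, seed=seed + 101)
        disp = self.contrast("dispersion", group_a, group_b, n_sub=n_sub,
                             B=B, seed=seed + 202)
        dist = self.contrast("distance_between", group_a, group_b,
                             n_sub=n_sub, B=B, seed=seed + 303)
        label = inference.classify_polarization(pos[best], ext, disp, alpha=alpha)
        return ClassificationReport(group_a=group_a, group_b=group_b,
                                    label=label, position=pos[best],
                                    position_axis=best, extremization=ext,
                                    dispersion=disp, distance=dist, alpha=alpha)

    # -- presentation --------------------------------------------------------
    def summary(self) -> str:
        """Plain-text summary of the fitted space and group metrics."""
        sp = self.space
        lines = ["Attitudinal space", "=" * 17]
        lines.append(f"respondents: {sp.n}    items: "
                     f"{len(self.table.items)}    axes: {sp.d}")
        lines.append(f"method: {sp.method}    rotation: {sp.rotation}")
        ve = ", ".join(f"axis {k + 1}: {v:.1%}"
                       for k, v in enumerate(sp.variance_explained))
        lines.append(f"variance explained: {ve}")
        if sp.cumulative_variance_unrotated is not None:
            lines.append("cumulative (unrotated): "
                         f"{sp.cumulative_variance_unrotated:.1%}")
        if sp.rotation == "promax" and sp.d >= 2:
            r = sp.interfactor_correlation[0, 1]
            lines.append(f"interfactor correlation (axes 1-2): {r:+.2f}")
        lines.append("")
        with pd.option_context("display.width", 120,
                               "display.float_format", "{:.3f}".format):
            lines.append(str(self.group_metrics()))
        return "\n".join(lines)

    def plot(self, ax=None, **scatter_kwargs):
        """Scatter of respondents in the scaled space, coloured by group."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        X = self.cloud.coordinates
        for g in self.cloud.group_labels():
            m = self.cloud.mask(g)
            ax.scatter(X[m, 0], X[m, 1] if self.cloud.d > 1 else np.zeros(m.sum()),
                       label=str(g), s=8, alpha=0.6, **scatter_kwargs)
        ax.set_xlabel("axis 1")
        ax.set_ylabel("axis 2" if self.cloud.d > 1 else "")
        ax.legend(title="group", fontsize="small")
        return ax
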