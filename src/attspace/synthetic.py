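"""Synthetic Likert surveys with known latent structure.

Respondents carry latent positions drawn from group-specific multivariate
normals in a low-dimensional attitude space; each questionnaire item is a
noisy linear readout of those positions, discretized into Likert levels by
thresholds placed at equally spaced normal quantiles of the pooled item
score.  Missingness is injected completely at random.  Ground-truth latent
positions are returned alongside the survey (never written into it), so
recovery of the attitudinal space can be tested end to end.

Named presets encode canonical polarization histories as two "time"
populations per social group (labels ``A@t1`` ... ``B@t2``):

* ``null``       two groups from one distribution (no polarization)
* ``weak``       positions separate over time while groups grow MORE
                 diffuse (inflated within-group covariance)
* ``strong``     positions separate while groups tighten around their own
                 means (shrunken covariance: alignment + homogeneity)
* ``case1_like`` positions separate AND covariance inflates, the pattern
                 where extremization and dispersion both increase
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .survey_io import ItemSpec, SurveyTable

__all__ = ["ScenarioConfig", "generate_survey", "preset_scenario", "PRESETS"]


@dataclass
class ScenarioConfig:
    """Generative parameters for one synthetic survey."""

    group_labels: tuple = ("A", "B")
    n_per_group: int = 500
    d_latent: int = 2
    group_means: dict = None            # label -> length-d vector
    group_covs: dict = None             # label -> d x d positive-definite
    n_items: int = 12
    loading_pattern: np.ndarray = None  # p x d; default simple structure, 0.8
    n_levels: int = 5
    thresholds: list = None             # per item, standardized units; default quantiles
    noise_sd: float = 0.6
    missing_rate: float = 0.0
    seed: int = 20230716

    def __post_init__(self):
        d, p = self.d_latent, self.n_items
        if self.group_means is None:
            self.group_means = {g: np.zeros(d) for g in self.group_labels}
        self.group_means = {g: np.asarray(v, dtype=float)
                            for g, v in self.group_means.items()}
        if self.group_covs is None:
            self.group_covs = {g: np.eye(d) for g in self.group_labels}
        self.group_covs = {g: np.asarray(v, dtype=float)
                           for g, v in self.group_covs.items()}
        for g in self.group_labels:
            cov = self.group_covs[g]
            if np.linalg.eigvalsh(cov).min() <= 0:
                raise ValueError(f"group {g!r}: covariance not positive-definite")
            if len(self.group_means[g]) != d:
                raise ValueError(f"group {g!r}: mean has wrong dimension")
        if self.loading_pattern is None:
            lam = np.zeros((p, d))
            for j in range(p):
                lam[j, j * d // p] = 0.8
            self.loading_pattern = lam
        self.loading_pattern = np.asarray(self.loading_pattern, dtype=float)
        if self.loading_pattern.shape != (p, d):
            raise ValueError("loading_pattern must be n_items x d_latent")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.thresholds is not None:
            for t in self.thresholds:
                tt = np.asarray(t, dtype=float)
                if np.any(np.diff(tt) <= 0):
                    raise ValueError("thresholds must be strictly increasing")

    def to_yaml(self, path) -> None:
        rec = asdict(self)
        rec["group_means"] = {g: v.tolist() for g, v in self.group_means.items()}
        rec["group_covs"] = {g: v.tolist() for g, v in self.group_covs.items()}
        rec["loading_pattern"] = self.loading_pattern.tolist()
        rec["group_labels"] = list(self.group_labels)
        with open(path, "w") as fh:
            yaml.safe_dump(rec, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            rec = yaml.safe_load(fh)
        rec["group_labels"] = tuple(rec["group_labels"])
        if rec.get("loading_pattern") is not None:
            rec["loading_pattern"] = np.asarray(rec["loading_pattern"])
        return cls(**rec)


def generate_survey(config: ScenarioConfig,
                    seed: int | None = None) -> tuple[SurveyTable, pd.DataFrame]:
    """Draw one survey from a scenario; returns (table, true latent positions).

    Item scores are ``latent @ loadings' + noise``, standardized by the
    item's REFERENCE scale (its sd under a standard-normal latent
    population) and cut at the item's thresholds into codes 1..L.  Default
    thresholds sit at normal quantiles k/L, k = 1..L-1: balanced categories
    for an unpolarized population.  The thresholds are a fixed property of
    the instrument — they do not adapt to the population being surveyed —
    so strongly separated groups genuinely saturate the scale ends, as
    polarized respondents do on real Likert items.  Missing cells are then
    blanked completely at random at ``missing_rate``.
    """
    from scipy import stats

    rng = np.random.default_rng(config.seed if seed is None else seed)
    p, d, L = config.n_items, config.d_latent, config.n_levels

    blocks, labels = [], []
    for g in config.group_labels:
        z = rng.multivariate_normal(config.group_means[g], config.group_covs[g],
                                    size=config.n_per_group)
        blocks.append(z)
        labels.extend([g] * config.n_per_group)
    Z = np.vstack(blocks)
    n = len(Z)
    Y = Z @ config.loading_pattern.T + config.noise_sd * rng.standard_normal((n, p))

    default_cuts = stats.norm.ppf(np.arange(1, L) / L)
    # fixed instrument scale: item sd under a standard-normal latent population
    ref_sd = np.sqrt((config.loading_pattern ** 2).sum(axis=1)
                     + config.noise_sd ** 2)
    codes = np.empty((n, p))
    for j in range(p):
        y = Y[:, j] / ref_sd[j]
        cuts = (np.asarray(config.thresholds[j], dtype=float)
                if config.thresholds is not None else default_cuts)
        codes[:, j] = np.searchsorted(cuts, y) + 1.0   # levels 1..L

    if config.missing_rate > 0:
        codes[rng.random((n, p)) < config.missing_rate] = np.nan

    ids = pd.Index([f"r{i:05d}" for i in range(n)], name="respondent_id")
    items = [ItemSpec(item_id=f"item_{j + 1:02d}", kind="ordinal",
                      level_codes=tuple(range(1, L + 1))) for j in range(p)]
    table = SurveyTable(
        responses=pd.DataFrame(codes, index=ids,
                               columns=[it.item_id for it in items]),
        groups=pd.Series(labels, index=ids, name="group"),
        items=items,
    )
    latents = pd.DataFrame(Z, index=ids,
                           columns=[f"latent_{k + 1}" for k in range(d)])
    latents.insert(0, "group", labels)
    return table, latents


def _two_time(mean_t1, mean_t2, cov_t1, cov_t2):
    """Symmetric A/B groups observed at two times."""
    m1, m2 = np.asarray(mean_t1, float), np.asarray(mean_t2, float)
    return (
        ("A@t1", "B@t1", "A@t2", "B@t2"),
        {"A@t1": -m1, "B@t1": m1, "A@t2": -m2, "B@t2": m2},
        {"A@t1": cov_t1, "B@t1": cov_t1, "A@t2": cov_t2, "B@t2": cov_t2},
    )


def _presets(n_per_group: int, seed: int) -> dict:
    I2 = np.eye(2)
    base = dict(n_per_group=n_per_group, seed=seed)
    # weak and strong share the same mean-separation history (a mild split
    # at t1 growing to camps that pin the ends of the first attitude
    # dimension at t2); they differ only in what happens to the
    # within-group covariance: strong tightens (homogeneous camps), weak
    # inflates (diffuse, unaligned groups).  Camps deliberately saturate
    # the Likert scale at t2, as heavily polarized respondents do.
    sep1, sep2 = (0.15, 0.0), (2.2, 0.0)
    out = {}
    out["null"] = ScenarioConfig(group_labels=("A", "B"), **base)
    for name, cov2 in (("weak", 1.5 * I2), ("strong", 0.08 * I2)):
        labels, means, covs = _two_time(sep1, sep2, 0.2 * I2, cov2)
        out[name] = ScenarioConfig(group_labels=labels, group_means=means,
                                   group_covs=covs, **base)
    # positions separate while groups also grow MORE heterogeneous
    labels, means, covs = _two_time((0.5, 0.0), (1.0, 0.0), 0.4 * I2, 0.8 * I2)
    out["case1_like"] = ScenarioConfig(group_labels=labels, group_means=means,
                                       group_covs=covs, **base)
    return out


PRESETS = ("null", "weak", "strong", "case1_like")


def preset_scenario(name: str, n_per_group: int = 500,
                    seed: int = 20230716) -> ScenarioConfig:
    """Named polarization scenario (see module docstring for the catalogue)."""
    presets = _presets(n_per_group, seed)
    if name not in presets:
        raise KeyError(f"unknown scenario {name!r}; choose from {PRESETS}")
    return presets[name]
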