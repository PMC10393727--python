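"""End-to-end run: config in, report bundle out.

A run config (YAML or dict) names the survey CSV, the item sidecar, the
construction choices and the bootstrap settings; :func:`run_pipeline`
executes filter -> impute -> dimensionality -> space -> scaling -> metrics
-> bootstrap contrasts -> classification, and writes

    coordinates.csv, loadings.csv, metrics.csv, contrasts.csv,
    report.json, run.log

under the output directory.  Every output records the package version, a
hash of the resolved config, and the seed, so a rerun with the same config
and seed is byte-identical.

Contrast pairs default to "auto": when group labels follow the
``<group>@<time>`` convention, each group is contrasted across consecutive
times (later vs earlier); otherwise all unordered group pairs are
contrasted.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .inference import DEFAULT_SEED
from .model import AttitudinalSpaceModel
from .survey_io import load_items, read_survey

logger = logging.getLogger("attspace")

__all__ = ["run_pipeline", "auto_pairs", "DEFAULT_CONFIG"]

DEFAULT_CONFIG = {
    "survey": None,              # path to survey CSV
    "items": None,               # path to YAML item sidecar
    "group_column": "group",
    "weight_column": None,
    "max_missing_frac": 0.10,
    "space": {"method": "pca", "rotation": "auto", "d": None},
    "bootstrap": {"B": 1000, "n_sub": None, "seed": DEFAULT_SEED, "alpha": 0.05},
    "contrasts": "auto",
    "normalize_by": "sqrt_d",
}


def auto_pairs(labels) -> list:
    """Contrast pairs implied by the group labels.

    ``X@t2`` vs ``X@t1`` per group when labels carry a time suffix,
    otherwise every unordered pair of plain labels.
    """
    labels = list(labels)
    timed = [lab for lab in labels if "@" in str(lab)]
    if timed and len(timed) == len(labels):
        by_group = {}
        for lab in labels:
            g, t = str(lab).rsplit("@", 1)
            by_group.setdefault(g, []).append((t, lab))
        pairs = []
        for g, entries in by_group.items():
            entries.sort()
            for (t0, a), (t1, b) in zip(entries, entries[1:]):
                pairs.append((b, a))        # later vs earlier
        return pairs
    return [(a, b) for i, a in enumerate(labels) for b in labels[i + 1:]]


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def run_pipeline(config: dict, outdir, table=None, items=None) -> dict:
    """Execute the full workflow; returns the report dict.

    ``table``/``items`` may be passed in-memory (e.g. straight from the
    synthetic generator); otherwise they are read from the paths in the
    config.
    """
    cfg = _merge(DEFAULT_CONFIG, config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]
    seed = int(cfg["bootstrap"]["seed"])
    logger.info("attspace %s  config %s  seed %d", __version__, cfg_hash, seed)

    try:
        if table is None:
            stage = "read"
            items = load_items(cfg["items"])
            table = read_survey(cfg["survey"], items, cfg["group_column"],
                                cfg.get("weight_column"))
        stage = "fit"
        model = AttitudinalSpaceModel(
            table, method=cfg["space"]["method"],
            rotation=cfg["space"]["rotation"], d=cfg["space"]["d"],
            max_missing_frac=cfg["max_missing_frac"],
            normalize_by=cfg["normalize_by"])
        res = model.fit()

        stage = "export"
        res.scores.to_csv(outdir / "coordinates.csv")
        if res.loadings is not None:
            res.loadings.to_csv(outdir / "loadings.csv")
        res.group_metrics().to_csv(outdir / "metrics.csv")

        stage = "contrasts"
        pairs = cfg["contrasts"]
        if pairs == "auto":
            pairs = auto_pairs(res.cloud.group_labels())
        B = int(cfg["bootstrap"]["B"])
        n_sub = cfg["bootstrap"]["n_sub"]
        alpha = float(cfg["bootstrap"]["alpha"])
        rows, reports = [], []
        for k, (a, b) in enumerate(pairs):
            rep = res.classify(a, b, n_sub=n_sub, B=B,
                               seed=seed + 1000 * k, alpha=alpha)
            reports.append(rep.to_dict())
            for name in ("position", "extremization", "dispersion", "distance"):
                c = getattr(rep, name)
                rows.append({"group_a": a, "group_b": b, "metric": c.metric,
                             "point_a": c.point_a, "point_b": c.point_b,
                             "delta": c.delta, "percent_change": c.percent_change,
                             "p_value": c.p_value, "direction": c.direction,
                             "classification": rep.label})
        pd.DataFrame(rows).to_csv(outdir / "contrasts.csv", index=False)

        report = {
            "version": __version__, "config_hash": cfg_hash, "seed": seed,
            "n": int(res.space.n), "d": int(res.space.d),
            "rotation": res.space.rotation, "method": res.space.method,
            "variance_explained": [float(v) for v in res.space.variance_explained],
            "cumulative_variance_unrotated": res.space.cumulative_variance_unrotated,
            "groups": {str(g): int((res.cloud.groups == g).sum())
                       for g in res.cloud.group_labels()},
            "classifications": reports,
        }
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        logger.info("pipeline complete: %d contrast pairs", len(pairs))
        return report
    except Exception as err:
        logger.error("pipeline failed at stage %r: %s", stage, err)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err
    finally:
        logger.removeHandler(handler)
        handler.close()


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
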