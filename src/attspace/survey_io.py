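"""Reading, validating, filtering and encoding respondent-by-item survey tables.

A survey is a CSV with one row per respondent, a group-label column, an
optional weight column, and one column per questionnaire item.  Items are
described by :class:`ItemSpec` records (ordinal Likert scales, 0-100 feeling
thermometers, or unordered categoricals), usually stored in a YAML sidecar
next to the CSV.  Missing answers are empty cells or a sentinel string,
never a numeric code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("attspace")

__all__ = [
    "ItemSpec",
    "SurveyTable",
    "SurveyValidationError",
    "read_survey",
    "load_items",
    "save_items",
    "filter_missing",
    "impute_missing",
    "standardize_items",
]

_KINDS = ("ordinal", "continuous", "categorical")


class SurveyValidationError(ValueError):
    """Raised when a survey file violates its item specification."""


@dataclass(frozen=True)
class ItemSpec:
    """Metadata for one questionnaire item.

    Parameters
    ----------
    item_id : str
        Column name in the survey CSV.
    kind : {"ordinal", "continuous", "categorical"}
        Measurement level.  Ordinal items carry 2-11 strictly increasing
        level codes (e.g. a 5-point Likert scale coded 1..5); continuous
        items carry finite ``bounds`` (e.g. a 0-100 feeling thermometer);
        categorical items carry unordered admissible codes and are only
        supported on the Gower/PCoA path.
    level_codes : tuple of float, optional
        Admissible codes for ordinal/categorical items.
    bounds : (float, float), optional
        Inclusive admissible range for continuous items.
    reverse_coded : bool
        If true the item is reflected (code -> min+max-code) before any
        numeric encoding, so that all items point the same way.
    """

    item_id: str
    kind: str = "ordinal"
    level_codes: tuple = ()
    bounds: tuple = (0.0, 100.0)
    reverse_coded: bool = False

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"item {self.item_id!r}: unknown kind {self.kind!r}")
        if self.kind in ("ordinal", "categorical"):
            codes = tuple(float(c) for c in self.level_codes)
            if not 2 <= len(codes) <= 11:
                raise ValueError(
                    f"item {self.item_id!r}: needs 2-11 level codes, got {len(codes)}"
                )
            if self.kind == "ordinal" and not all(
                a < b for a, b in zip(codes, codes[1:])
            ):
                raise ValueError(
                    f"item {self.item_id!r}: level codes must be strictly increasing"
                )
            object.__setattr__(self, "level_codes", codes)
        else:
            lo, hi = (float(b) for b in self.bounds)
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(
                    f"item {self.item_id!r}: continuous bounds must be finite and increasing"
                )
            object.__setattr__(self, "bounds", (lo, hi))

    @property
    def n_levels(self) -> int | None:
        """Number of admissible codes (ordinal/categorical items only)."""
        return len(self.level_codes) if self.kind != "continuous" else None

    def admissible(self, values: np.ndarray) -> np.ndarray:
        """Boolean mask of which (non-missing) values are legal codes."""
        v = np.asarray(values, dtype=float)
        ok = np.isnan(v)  # missing cells are not this check's business
        if self.kind == "continuous":
            lo, hi = self.bounds
            return ok | ((v >= lo) & (v <= hi))
        return ok | np.isin(v, np.asarray(self.level_codes))

    def reflect(self, values: np.ndarray) -> np.ndarray:
        """Reverse-code values: code -> (min + max - code) on the item's scale."""
        v = np.asarray(values, dtype=float)
        if self.kind == "continuous":
            lo, hi = self.bounds
        else:
            lo, hi = self.level_codes[0], self.level_codes[-1]
        return lo + hi - v


@dataclass
class SurveyTable:
    """Validated survey data: responses, group labels and optional weights.

    ``responses`` is a float DataFrame (respondents x items) with NaN as the
    explicit missing marker; ``respondent_id`` is its index.  ``imputed``
    marks cells filled by :func:`impute_missing`.
    """

    responses: pd.DataFrame
    groups: pd.Series
    items: list
    weights: pd.Series = None
    imputed: pd.DataFrame = None

    def __post_init__(self):
        if self.weights is None:
            self.weights = pd.Series(1.0, index=self.responses.index, name="weight")
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any():
            raise SurveyValidationError("weights must be nonnegative")
        for g, wsum in self.weights.groupby(self.groups).sum().items():
            if wsum <= 0:
                raise SurveyValidationError(f"group {g!r}: weights sum to 0")
        if self.imputed is None:
            self.imputed = pd.DataFrame(
                False, index=self.responses.index, columns=self.responses.columns
            )

    # -- convenience accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.responses)

    @property
    def item_ids(self) -> list:
        return [it.item_id for it in self.items]

    @property
    def group_labels(self) -> list:
        return list(pd.unique(self.groups))

    def missing_fraction(self) -> pd.Series:
        """Per-respondent fraction of missing items."""
        return self.responses.isna().mean(axis=1)

    def is_complete(self) -> bool:
        return not self.responses.isna().any().any()

    def item(self, item_id: str) -> ItemSpec:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    def subset(self, index) -> "SurveyTable":
        """Row subset preserving order; shares item metadata."""
        return SurveyTable(
            responses=self.responses.loc[index],
            groups=self.groups.loc[index],
            items=self.items,
            weights=self.weights.loc[index],
            imputed=self.imputed.loc[index],
        )


# ---------------------------------------------------------------------------
# item sidecar


def load_items(path) -> list:
    """Read a YAML/JSON sidecar listing ItemSpec fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    items = []
    for rec in raw["items"] if isinstance(raw, dict) else raw:
        items.append(
            ItemSpec(
                item_id=str(rec["item_id"]),
                kind=rec.get("kind", "ordinal"),
                level_codes=tuple(rec.get("level_codes", ())),
                bounds=tuple(rec.get("bounds", (0.0, 100.0))),
                reverse_coded=bool(rec.get("reverse_coded", False)),
            )
        )
    return items


def save_items(items, path) -> None:
    recs = []
    for it in items:
        rec = {"item_id": it.item_id, "kind": it.kind, "reverse_coded": it.reverse_coded}
        if it.kind == "continuous":
            rec["bounds"] = list(it.bounds)
        else:
            rec["level_codes"] = [float(c) for c in it.level_codes]
        recs.append(rec)
    with open(path, "w") as fh:
        yaml.safe_dump({"items": recs}, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# reading and validation


def read_survey(
    path,
    items,
    group_column: str,
    weight_column: str | None = None,
    id_column: str | None = None,
    missing_values: tuple = ("", "NA", "NaN", "nan"),
) -> SurveyTable:
    """Read a survey CSV and validate every cell against its ItemSpec.

    Raises :class:`SurveyValidationError` listing every offending cell
    (row label + item id) if any non-missing code is outside its item's
    admissible set, if the group column is absent, or if an item column
    is missing from the file.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if group_column not in df.columns:
        raise SurveyValidationError(f"group column {group_column!r} not in file")
    if id_column is not None and id_column in df.columns:
        df = df.set_index(id_column)
    else:
        df.index = df.index.astype(str)
    df.index.name = "respondent_id"

    missing = {str(m) for m in missing_values}
    bad_cells = []
    cols = {}
    for it in items:
        if it.item_id not in df.columns:
            raise SurveyValidationError(f"unknown item id {it.item_id!r}: not in file")
        raw = df[it.item_id].astype(str).str.strip()
        col = pd.to_numeric(raw.where(~raw.isin(missing)), errors="coerce")
        # strings that are neither missing nor numeric are invalid codes
        invalid = col.isna() & ~raw.isin(missing)
        ok = it.admissible(col.to_numpy())
        for rid in df.index[invalid | ~ok]:
            bad_cells.append((rid, it.item_id, raw.loc[rid]))
        cols[it.item_id] = col
    if bad_cells:
        listing = "; ".join(f"row {r!r} item {i!r} value {v!r}" for r, i, v in bad_cells[:20])
        more = "" if len(bad_cells) <= 20 else f" (+{len(bad_cells) - 20} more)"
        raise SurveyValidationError(f"{len(bad_cells)} invalid cells: {listing}{more}")

    responses = pd.DataFrame(cols, index=df.index)
    groups = df[group_column].astype(str).rename("group")
    weights = None
    if weight_column is not None:
        if weight_column not in df.columns:
            raise SurveyValidationError(f"weight column {weight_column!r} not in file")
        weights = pd.to_numeric(df[weight_column]).astype(float).rename("weight")
    table = SurveyTable(responses=responses, groups=groups, items=list(items), weights=weights)
    logger.info("read %d respondents, %d items from %s", table.n, len(items), path)
    return table


def write_survey(table: SurveyTable, path, group_column: str = "group",
                 weight_column: str | None = "weight") -> None:
    """Write a SurveyTable back to CSV (empty cell = missing)."""
    out = table.responses.copy()
    out.insert(0, group_column, table.groups)
    if weight_column:
        out.insert(1, weight_column, table.weights)
    out.to_csv(path, index=True)


# ---------------------------------------------------------------------------
# filtering, imputation, encoding


def filter_missing(table: SurveyTable, max_missing_frac: float = 0.10) -> SurveyTable:
    """Drop respondents with MORE than ``max_missing_frac`` missing items.

    A respondent at exactly the threshold is retained.  Idempotent; row
    order preserved.  Errors if nobody survives.
    """
    if not 0 <= max_missing_frac < 1:
        raise ValueError("max_missing_frac must be in [0, 1)")
    frac = table.missing_fraction()
    keep = frac <= max_missing_frac + 1e-12
    kept = table.subset(table.responses.index[keep])
    if kept.n == 0:
        raise SurveyValidationError(
            f"no respondents have <= {max_missing_frac:.0%} missing items; "
            "relax max_missing_frac"
        )
    for g in table.group_labels:
        before = int((table.groups == g).sum())
        after = int((kept.groups == g).sum())
        logger.info("filter_missing: group %s %d -> %d respondents", g, before, after)
    return kept


def impute_missing(table: SurveyTable) -> SurveyTable:
    """Fill residual missing cells with the per-item median of observed values.

    Ordinal items round the median to the nearest admissible level code;
    continuous items use the plain median.  Imputed cells are flagged in
    ``table.imputed``.  An item with no observed value at all is an error.
    """
    responses = table.responses.copy()
    imputed = table.imputed.copy()
    for it in table.items:
        col = responses[it.item_id]
        if col.isna().all():
            raise SurveyValidationError(f"item {it.item_id!r} is entirely missing")
        if not col.isna().any():
            continue
        med = float(col.median())
        if it.kind != "continuous":
            codes = np.asarray(it.level_codes)
            med = float(codes[np.argmin(np.abs(codes - med))])
        mask = col.isna()
        responses.loc[mask, it.item_id] = med
        imputed.loc[mask, it.item_id] = True
        logger.debug("imputed %d cells of %s with %g", int(mask.sum()), it.item_id, med)
    return replace(table, responses=responses, imputed=imputed)


def standardize_items(table: SurveyTable) -> np.ndarray:
    """Numerically encode a complete table as column z-scores (ddof=1).

    Reverse-coded items are reflected on their own scale first.  Returns an
    ``n x p`` float array in the order of ``table.items``.  A zero-variance
    item is an error (it carries no information for the space).
    """
    if not table.is_complete():
        raise SurveyValidationError("table has missing cells; filter/impute first")
    cols = []
    for it in table.items:
        v = table.responses[it.item_id].to_numpy(dtype=float)
        if it.reverse_coded:
            v = it.reflect(v)
        sd = v.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise SurveyValidationError(f"item {it.item_id!r} has zero variance")
        cols.append((v - v.mean()) / sd)
    return np.column_stack(cols)
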