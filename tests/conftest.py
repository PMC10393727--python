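import numpy as np
import pandas as pd
import pytest

from attspace.metrics import ScaledCloud
from attspace.survey_io import ItemSpec, SurveyTable


def make_cloud(coords, groups=None, weights=None, normalizer=None):
    """ScaledCloud straight from coordinates (bypasses min-max scaling)."""
    coords = np.asarray(coords, dtype=float)
    n, d = coords.shape
    if groups is None:
        groups = np.array(["g"] * n, dtype=object)
    else:
        groups = np.asarray(list(groups), dtype=object)
    if weights is None:
        weights = np.ones(n)
    return ScaledCloud(
        coordinates=coords, groups=groups, weights=np.asarray(weights, float),
        axis_min=coords.min(axis=0), axis_max=coords.max(axis=0),
        normalizer=float(np.sqrt(d)) if normalizer is None else normalizer,
    )


def make_table(codes, groups, n_levels=5, weights=None, item_kinds=None):
    """SurveyTable from a code matrix (NaN = missing)."""
    codes = np.asarray(codes, dtype=float)
    n, p = codes.shape
    items = []
    for j in range(p):
        kind = item_kinds[j] if item_kinds else "ordinal"
        if kind == "continuous":
            items.append(ItemSpec(f"it{j}", kind="continuous", bounds=(0, 100)))
        else:
            items.append(ItemSpec(f"it{j}", kind=kind,
                                  level_codes=tuple(range(1, n_levels + 1))))
    ids = pd.Index([f"r{i}" for i in range(n)], name="respondent_id")
    return SurveyTable(
        responses=pd.DataFrame(codes, index=ids, columns=[it.item_id for it in items]),
        groups=pd.Series(list(groups), index=ids, name="group"),
        items=items,
        weights=None if weights is None else pd.Series(list(weights), index=ids),
    )


@pytest.fixture
def unit_square_cloud():
    return make_cloud([[0, 0], [0, 1], [1, 0], [1, 1]])


@pytest.fixture
def rng():
    return np.random.default_rng(20230716)
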