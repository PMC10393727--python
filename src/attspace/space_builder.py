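"""Construction of the low-dimensional attitudinal space.

The default route mirrors the two-stage recipe used for ordinal/numeric
surveys: (1) factor the polychoric/polyserial correlation matrix only to
decide how many axes carry signal (eigenvalue > 1 rule), then (2) run a
principal component analysis on the z-scored item codes, retain the chosen
axes and rotate them (varimax for orthogonal simple structure, promax when
the axes are substantially correlated).  Scores are recomputed under the
rotation so that respondents' coordinates live on the rotated axes.

For tables that mix categorical items or retain missing cells, the
alternative route builds a Gower dissimilarity matrix and embeds it with
principal coordinates analysis (Lingoes correction for negative
eigenvalues).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .correlations import CorrelationMatrix, correlation_matrix
from .survey_io import SurveyTable, standardize_items

logger = logging.getLogger("attspace")

__all__ = [
    "AttitudinalSpace",
    "RotationResult",
    "varimax",
    "promax",
    "rotate_loadings",
    "select_dimensionality",
    "build_space",
    "gower_matrix",
    "build_space_gower",
]


@dataclass
class RotationResult:
    loadings: np.ndarray              # p x d pattern loadings after rotation
    rotation: str                     # none | varimax | promax
    rotation_matrix: np.ndarray       # d x d transform applied to loadings
    interfactor_correlation: np.ndarray  # d x d; identity unless promax


@dataclass
class AttitudinalSpace:
    """Respondent coordinates and the item structure that generated them."""

    scores: np.ndarray                    # n x d
    respondent_ids: pd.Index
    groups: pd.Series
    weights: pd.Series
    loadings: pd.DataFrame | None         # p x d (None for the Gower route)
    variance_explained: np.ndarray        # d per-axis proportions
    rotation: str
    rotation_matrix: np.ndarray | None
    interfactor_correlation: np.ndarray
    eigenvalues: np.ndarray
    method: str = "pca"
    cumulative_variance_unrotated: float | None = None

    @property
    def d(self) -> int:
        return self.scores.shape[1]

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    def scores_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.scores,
            index=self.respondent_ids,
            columns=[f"axis_{k + 1}" for k in range(self.d)],
        )
        df.insert(0, "group", self.groups.to_numpy())
        return df

    def export(self, outdir, stem: str = "space") -> None:
        """Write coordinates, loadings and JSON metadata under ``outdir``."""
        import json
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.scores_frame().to_csv(outdir / f"{stem}_coordinates.csv")
        if self.loadings is not None:
            self.loadings.to_csv(outdir / f"{stem}_loadings.csv")
        meta = {
            "method": self.method,
            "rotation": self.rotation,
            "d": self.d,
            "variance_explained": [float(v) for v in self.variance_explained],
            "cumulative_variance_unrotated": self.cumulative_variance_unrotated,
            "interfactor_correlation": self.interfactor_correlation.tolist(),
        }
        with open(outdir / f"{stem}_meta.json", "w") as fh:
            json.dump(meta, fh, indent=2)


# ---------------------------------------------------------------------------
# rotations


def varimax_criterion(loadings: np.ndarray, kaiser: bool = True) -> float:
    """Raw varimax criterion: summed column variances of squared loadings."""
    L = np.asarray(loadings, dtype=float)
    if kaiser:
        h = np.sqrt((L ** 2).sum(axis=1))
        h[h == 0] = 1.0
        L = L / h[:, None]
    sq = L ** 2
    return float(np.sum(sq.var(axis=0)))


def varimax(loadings: np.ndarray, kaiser: bool = True, tol: float = 1e-12,
            max_iter: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal varimax rotation (Kaiser row-normalization by default).

    Returns (rotated loadings, d x d orthogonal rotation matrix).
    """
    L = np.asarray(loadings, dtype=float).copy()
    p, k = L.shape
    h = np.ones(p)
    if kaiser:
        h = np.sqrt((L ** 2).sum(axis=1))
        h[h == 0] = 1.0
        L = L / h[:, None]
    R = np.eye(k)
    crit = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (Lr ** 3 - Lr @ np.diag((Lr ** 2).sum(axis=0)) / p)
        )
        R = u @ vt
        new = s.sum()
        if new <= crit * (1.0 + tol):
            break
        crit = new
    return (L @ R) * h[:, None], R


def promax(loadings: np.ndarray, power: int = 4,
           kaiser: bool = True) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Oblique promax rotation: varimax followed by a power-target transform.

    Returns (pattern loadings, total transform matrix, interfactor
    correlation Phi).  Convention matches the classic definition: target
    ``Q = V * |V|**(power-1)`` built from the varimax solution V, least
    squares transform column-normalized so the implied factors have unit
    variance; ``Phi = inv(U'U)``.
    """
    Lv, Rv = varimax(loadings, kaiser=kaiser)
    Q = Lv * np.abs(Lv) ** (power - 1)
    U, *_ = np.linalg.lstsq(Lv, Q, rcond=None)
    d = np.diag(np.linalg.inv(U.T @ U))
    U = U * np.sqrt(d)[None, :]
    pattern = Lv @ U
    phi = np.linalg.inv(U.T @ U)
    phi = (phi + phi.T) / 2.0
    return pattern, Rv @ U, phi


def rotate_loadings(loadings: np.ndarray, method: str = "varimax",
                    promax_power: int = 4) -> RotationResult:
    """Rotate a p x d loading matrix for interpretability.

    d = 1 is a no-op with a warning (nothing to rotate).
    """
    L = np.asarray(loadings, dtype=float)
    p, d = L.shape
    if d == 1 or method == "none":
        if d == 1 and method != "none":
            warnings.warn("d=1: rotation is a no-op", stacklevel=2)
        return RotationResult(L.copy(), "none", np.eye(d), np.eye(d))
    if p <= d:
        raise ValueError("need more items than axes to rotate")
    if method == "varimax":
        Lr, R = varimax(L)
        return RotationResult(Lr, "varimax", R, np.eye(d))
    if method == "promax":
        pattern, T, phi = promax(L, power=promax_power)
        return RotationResult(pattern, "promax", T, phi)
    raise ValueError(f"unknown rotation {method!r}")


# ---------------------------------------------------------------------------
# dimensionality


def select_dimensionality(corr) -> int:
    """Number of axes to retain: count of eigenvalues strictly greater than 1.

    Falls back to 1 (with a warning) when no eigenvalue exceeds 1.
    """
    if isinstance(corr, CorrelationMatrix):
        vals = corr.eigenvalues()
    else:
        vals = np.linalg.eigvalsh(np.asarray(corr, dtype=float))
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite eigenvalues")
    d = int(np.sum(vals > 1.0))
    if d == 0:
        warnings.warn("no eigenvalue exceeds 1; retaining a single axis",
                      stacklevel=2)
        return 1
    return d


# ---------------------------------------------------------------------------
# PCA route


def _apply_sign_convention(loadings, scores, phi):
    """Flip each axis so its largest-|loading| item loads positively.

    Ties break toward the lowest item index.  Resolves the sign
    indeterminacy of PCA/rotation so scores are reproducible.
    """
    d = loadings.shape[1]
    flips = np.ones(d)
    for j in range(d):
        col = loadings[:, j]
        top = int(np.argmax(np.abs(col)))  # argmax takes the first maximum
        if col[top] < 0:
            flips[j] = -1.0
    loadings = loadings * flips[None, :]
    scores = scores * flips[None, :]
    phi = phi * np.outer(flips, flips)
    return loadings, scores, phi


def build_space(table: SurveyTable, items=None, rotation: str = "auto",
                d: int | None = None, promax_power: int = 4,
                corr: CorrelationMatrix | None = None) -> AttitudinalSpace:
    """Build the attitudinal space by rotated PCA on z-scored item codes.

    Parameters
    ----------
    table : SurveyTable
        Complete (filtered and imputed) survey table.
    rotation : {"none", "varimax", "promax", "auto"}
        "auto" fits promax and keeps it when the absolute interfactor
        correlation reaches 0.3, otherwise reverts to varimax.
    d : int, optional
        Number of axes.  When omitted, the eigenvalue-greater-than-1 rule is
        applied to the mixed-type (polychoric) correlation matrix.
    corr : CorrelationMatrix, optional
        Precomputed correlation matrix for dimensionality selection.
    """
    items = list(items if items is not None else table.items)
    X = standardize_items(table)  # raises on missing cells / zero variance
    n, p = X.shape
    if d is None:
        if corr is None:
            corr = correlation_matrix(table, items)
        d = select_dimensionality(corr)
        logger.info("eigenvalue>1 rule on the %s matrix retained d=%d axes",
                    "smoothed" if corr.smoothed else "mixed-type", d)
    if not 1 <= d <= p:
        raise ValueError(f"d={d} outside [1, p={p}]")

    # PCA via SVD of the standardized matrix
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    eigvals = s ** 2 / (n - 1)                  # eigenvalues of the correlation matrix
    load_full = Vt.T * np.sqrt(eigvals)[None, :]
    loadings = load_full[:, :d]
    scores = (U[:, :d] * np.sqrt(n - 1))        # unit-variance component scores
    cum_unrot = float(eigvals[:d].sum() / p)

    if rotation == "auto":
        if d >= 2:
            _, _, phi_try = promax(loadings, power=promax_power)
            off = np.abs(phi_try[~np.eye(d, dtype=bool)]).max()
            rotation = "promax" if off >= 0.3 else "varimax"
            logger.info("auto rotation: max |interfactor r| = %.3f -> %s",
                        off, rotation)
        else:
            rotation = "none"
    rot = rotate_loadings(loadings, method=rotation, promax_power=promax_power)

    if rot.rotation == "promax":
        # oblique scores: F_p = F @ inv(T)' has unit variances and correlation Phi
        rscores = scores @ np.linalg.inv(rot.rotation_matrix).T
    else:
        rscores = scores @ rot.rotation_matrix
    rload, rscores, phi = _apply_sign_convention(rot.loadings, rscores,
                                                 rot.interfactor_correlation)

    if rot.rotation == "promax":
        structure = rload @ phi
    else:
        structure = rload
    var_exp = (structure ** 2).sum(axis=0) / p

    ids = [it.item_id for it in items]
    return AttitudinalSpace(
        scores=rscores,
        respondent_ids=table.responses.index,
        groups=table.groups,
        weights=table.weights,
        loadings=pd.DataFrame(rload, index=ids,
                              columns=[f"axis_{k + 1}" for k in range(d)]),
        variance_explained=var_exp,
        rotation=rot.rotation,
        rotation_matrix=rot.rotation_matrix,
        interfactor_correlation=phi,
        eigenvalues=eigvals,
        method="pca",
        cumulative_variance_unrotated=cum_unrot,
    )


# ---------------------------------------------------------------------------
# Gower + PCoA route


def gower_matrix(table: SurveyTable, items=None) -> np.ndarray:
    """Pairwise Gower dissimilarity tolerating missing values.

    Ordinal and continuous items contribute range-scaled absolute
    differences; categorical items contribute simple mismatch.  Missing
    cells are dropped pairwise; a respondent pair with no comparable item
    at all is an error.
    """
    items = list(items if items is not None else table.items)
    n = table.n
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for it in items:
        v = table.responses[it.item_id].to_numpy(dtype=float)
        if it.reverse_coded:
            v = it.reflect(v)
        obs = ~np.isnan(v)
        both = np.outer(obs, obs)
        if it.kind == "categorical":
            contrib = (v[:, None] != v[None, :]).astype(float)
        else:
            rng = np.nanmax(v) - np.nanmin(v)
            if rng == 0 or not np.isfinite(rng):
                continue  # constant item: no information, Gower convention
            contrib = np.abs(v[:, None] - v[None, :]) / rng
        num += np.where(both, np.nan_to_num(contrib), 0.0)
        den += both
    offdiag = ~np.eye(n, dtype=bool)
    if np.any(den[offdiag] == 0):
        raise ValueError("some respondent pair shares no observed item")
    D = num / np.where(den > 0, den, 1.0)
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


def _pcoa(D: np.ndarray, d: int) -> tuple[np.ndarray, np.ndarray]:
    """Principal coordinates with Lingoes correction for negative eigenvalues."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n

    def center(Dsq):
        return -0.5 * J @ Dsq @ J

    B = center(D ** 2)
    vals = np.linalg.eigvalsh(B)
    if vals.min() < -1e-8 * max(1.0, vals.max()):
        # Lingoes: adding 2c to off-diagonal squared dissimilarities makes
        # the matrix Euclidean, with c = -smallest eigenvalue
        c = -vals.min()
        Dsq = D ** 2 + 2.0 * c
        np.fill_diagonal(Dsq, 0.0)
        B = center(Dsq)
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = np.clip(vals, 0.0, None)
    pos[pos < 1e-12 * max(pos.max(), 1e-300)] = 0.0  # numerically-zero axes
    coords = vecs[:, :d] * np.sqrt(pos[:d])[None, :]
    return coords, vals


def build_space_gower(table: SurveyTable, items=None, d: int = 2) -> AttitudinalSpace:
    """Build the space from Gower dissimilarities via PCoA.

    Accepts missing cells and categorical items; no imputation needed.
    ``variance_explained`` comes from the (corrected) positive eigenvalues.
    """
    items = list(items if items is not None else table.items)
    D = gower_matrix(table, items)
    if not 1 <= d < table.n:
        raise ValueError(f"d={d} outside [1, n-1]")
    coords, vals = _pcoa(D, d)
    pos = np.clip(vals, 0.0, None)
    total = pos.sum()
    var_exp = pos[:d] / total if total > 0 else np.zeros(d)
    # sign convention: largest-|coordinate| respondent positive per axis
    for j in range(d):
        top = int(np.argmax(np.abs(coords[:, j])))
        if coords[top, j] < 0:
            coords[:, j] = -coords[:, j]
    return AttitudinalSpace(
        scores=coords,
        respondent_ids=table.responses.index,
        groups=table.groups,
        weights=table.weights,
        loadings=None,
        variance_explained=var_exp,
        rotation="none",
        rotation_matrix=None,
        interfactor_correlation=np.eye(d),
        eigenvalues=vals,
        method="gower",
        cumulative_variance_unrotated=float(var_exp.sum()),
    )
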