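"""Mixed-type correlation estimation for ordinal and continuous survey items.

Ordinal-ordinal pairs use the two-step polychoric estimator: thresholds are
fixed from the marginal cumulative proportions via the inverse normal CDF,
then the latent correlation rho is found by one-dimensional maximum
likelihood over bivariate-normal rectangle probabilities.  Ordinal-continuous
pairs use the analogous two-step polyserial ML; continuous-continuous pairs
use Pearson.  The assembled matrix is smoothed to near positive
semi-definiteness when pairwise estimation leaves small negative eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "CorrelationMatrix",
    "polychoric_rho",
    "polyserial_rho",
    "correlation_matrix",
]

_RHO_BOUND = 0.999
_INF = 12.0  # Phi(12) == 1 to double precision; stands in for +inf thresholds


class EstimationError(RuntimeError):
    """A pairwise correlation could not be estimated."""


@dataclass
class CorrelationMatrix:
    """Symmetric item correlation matrix with per-pair method bookkeeping."""

    matrix: np.ndarray           # p x p, unit diagonal
    item_ids: list
    method: np.ndarray           # p x p object array: polychoric/polyserial/pearson
    smoothed: bool = False       # near-PSD repair applied

    def eigenvalues(self) -> np.ndarray:
        vals = np.linalg.eigvalsh(self.matrix)
        if not np.all(np.isfinite(vals)):
            raise EstimationError("non-finite eigenvalues in correlation matrix")
        return vals


def _ordinal_thresholds(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Level codes and interior normal thresholds from marginal proportions."""
    levels, counts = np.unique(x, return_counts=True)
    if len(levels) < 2:
        raise EstimationError("degenerate margin: fewer than 2 observed levels")
    cum = np.cumsum(counts)[:-1] / counts.sum()
    return levels, stats.norm.ppf(cum)


def _rectangle_probs(tx: np.ndarray, ty: np.ndarray, rho: float) -> np.ndarray:
    """Cell probabilities of a bivariate normal over a threshold grid."""
    gx = np.concatenate(([-_INF], tx, [_INF]))
    gy = np.concatenate(([-_INF], ty, [_INF]))
    xx, yy = np.meshgrid(gx, gy, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    cov = np.array([[1.0, rho], [rho, 1.0]])
    cdf = stats.multivariate_normal.cdf(pts, mean=np.zeros(2), cov=cov)
    cdf = np.asarray(cdf).reshape(len(gx), len(gy))
    cell = cdf[1:, 1:] - cdf[:-1, 1:] - cdf[1:, :-1] + cdf[:-1, :-1]
    return np.clip(cell, 1e-300, None)


def polychoric_rho(x, y) -> float:
    """Two-step polychoric correlation of two ordinal vectors.

    Pairs with a missing value in either vector are dropped.  Requires at
    least 20 complete pairs and two observed levels per margin.  The
    estimate is clamped to |rho| <= 0.999.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 20:
        raise EstimationError(f"only {len(x)} complete pairs; need >= 20")
    xlev, tx = _ordinal_thresholds(x)
    ylev, ty = _ordinal_thresholds(y)
    # contingency table of observed level combinations
    xi = np.searchsorted(xlev, x)
    yi = np.searchsorted(ylev, y)
    table = np.zeros((len(xlev), len(ylev)))
    np.add.at(table, (xi, yi), 1.0)

    def nll(rho):
        return -np.sum(table * np.log(_rectangle_probs(tx, ty, rho)))

    res = optimize.minimize_scalar(
        nll, bounds=(-_RHO_BOUND, _RHO_BOUND), method="bounded",
        options={"xatol": 1e-6},
    )
    if not res.success:
        raise EstimationError(f"polychoric ML did not converge: {res.message}")
    return float(np.clip(res.x, -_RHO_BOUND, _RHO_BOUND))


def polyserial_rho(cont, ordi) -> float:
    """Two-step polyserial correlation of a continuous and an ordinal vector."""
    z = np.asarray(cont, dtype=float)
    y = np.asarray(ordi, dtype=float)
    keep = ~(np.isnan(z) | np.isnan(y))
    z, y = z[keep], y[keep]
    if len(z) < 20:
        raise EstimationError(f"only {len(z)} complete pairs; need >= 20")
    sd = z.std(ddof=1)
    if sd == 0:
        raise EstimationError("continuous margin has zero variance")
    z = (z - z.mean()) / sd
    ylev, ty = _ordinal_thresholds(y)
    yi = np.searchsorted(ylev, y)
    tau = np.concatenate(([-_INF], ty, [_INF]))
    lo, hi = tau[yi], tau[yi + 1]

    def nll(rho):
        s = np.sqrt(1.0 - rho * rho)
        p = stats.norm.cdf((hi - rho * z) / s) - stats.norm.cdf((lo - rho * z) / s)
        return -np.sum(np.log(np.clip(p, 1e-300, None)))

    res = optimize.minimize_scalar(
        nll, bounds=(-_RHO_BOUND, _RHO_BOUND), method="bounded",
        options={"xatol": 1e-6},
    )
    if not res.success:
        raise EstimationError(f"polyserial ML did not converge: {res.message}")
    return float(np.clip(res.x, -_RHO_BOUND, _RHO_BOUND))


def _near_psd(mat: np.ndarray, floor: float = 1e-8) -> tuple[np.ndarray, bool]:
    """Clip negative eigenvalues and restore unit diagonal."""
    vals, vecs = np.linalg.eigh(mat)
    if vals.min() >= -floor:
        return mat, False
    vals = np.clip(vals, floor, None)
    fixed = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    fixed = (fixed + fixed.T) / 2.0
    np.fill_diagonal(fixed, 1.0)
    return fixed, True


def correlation_matrix(table, items=None) -> CorrelationMatrix:
    """Pairwise mixed-type correlation matrix of a survey table.

    Dispatch per pair: polychoric (ordinal-ordinal), polyserial
    (ordinal-continuous), Pearson (continuous-continuous), with pairwise
    deletion of missing values.  Any pairwise failure raises an error
    naming the offending item pair.
    """
    items = list(items if items is not None else table.items)
    p = len(items)
    ids = [it.item_id for it in items]
    cols = {}
    for it in items:
        if it.kind == "categorical":
            raise EstimationError(
                f"item {it.item_id!r} is categorical; use the Gower builder"
            )
        v = table.responses[it.item_id].to_numpy(dtype=float)
        if it.reverse_coded:
            v = it.reflect(v)
        cols[it.item_id] = v

    mat = np.eye(p)
    method = np.empty((p, p), dtype=object)
    np.fill_diagonal(method, "identity")
    for i in range(p):
        for j in range(i + 1, p):
            a, b = items[i], items[j]
            x, y = cols[a.item_id], cols[b.item_id]
            try:
                if a.kind == "ordinal" and b.kind == "ordinal":
                    r, how = polychoric_rho(x, y), "polychoric"
                elif a.kind == "continuous" and b.kind == "continuous":
                    keep = ~(np.isnan(x) | np.isnan(y))
                    r, how = float(stats.pearsonr(x[keep], y[keep])[0]), "pearson"
                elif a.kind == "continuous":
                    r, how = polyserial_rho(x, y), "polyserial"
                else:
                    r, how = polyserial_rho(y, x), "polyserial"
            except EstimationError as err:
                raise EstimationError(
                    f"pair ({a.item_id!r}, {b.item_id!r}): {err}"
                ) from err
            mat[i, j] = mat[j, i] = r
            method[i, j] = method[j, i] = how
    mat, smoothed = _near_psd(mat)
    return CorrelationMatrix(matrix=mat, item_ids=ids, method=method, smoothed=smoothed)
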