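"""Ordinary kriging of vessel fields.

Per-cell vessel speed, draft and beam are interpolated from AIS point
reports by ordinary kriging: an isotropic variogram is fitted to the
empirical semivariances by weighted least squares, then the OK system
is solved per prediction point over a nearest-neighborhood of samples.
Predictions are validated against the input data range — values outside
the range are clamped and logged, mirroring the range check one applies
to any kriged surface of physically bounded quantities — and the kriging
standard error accompanies every prediction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

log = logging.getLogger(__name__)

__all__ = ["VariogramSpec", "KrigingResult", "fit_variogram", "krige_field"]


def _spherical(h, nugget, psill, rng):
    hr = np.minimum(h / rng, 1.0)
    return nugget + psill * (1.5 * hr - 0.5 * hr**3)


def _exponential(h, nugget, psill, rng):
    return nugget + psill * (1.0 - np.exp(-3.0 * h / rng))


def _gaussian(h, nugget, psill, rng):
    return nugget + psill * (1.0 - np.exp(-3.0 * (h / rng) ** 2))


_MODELS: dict[str, Callable] = {
    "spherical": _spherical,
    "exponential": _exponential,
    "gaussian": _gaussian,
}


@dataclass
class VariogramSpec:
    """Variogram model and parameters.

    ``fit_mode='auto'`` estimates (nugget, sill, range) from the data;
    ``'fixed'`` uses the supplied values as-is. The semivariance at lag h
    is nugget + partial-sill * model(h / range); ``sill`` here is the
    partial sill.
    """

    model: Literal["spherical", "exponential", "gaussian"] = "spherical"
    nugget: float = 0.0
    sill: float = 1.0
    range: float = 1.0
    fit_mode: Literal["auto", "fixed"] = "auto"

    def __post_init__(self):
        if self.nugget < 0 or self.sill < 0 or self.range <= 0:
            raise ValueError("variogram parameters out of range")

    def gamma(self, h):
        return _MODELS[self.model](np.asarray(h, dtype=float), self.nugget, self.sill, self.range)


@dataclass
class KrigingResult:
    predicted: np.ndarray
    std_error: np.ndarray
    spec: VariogramSpec
    n_clamped: int = 0
    method: str = "ordinary_kriging"


def _average_duplicates(xy: np.ndarray, values: np.ndarray):
    """Average values observed at identical coordinates (avoids a singular OK system)."""
    key = np.round(xy, 6)
    uniq, inverse = np.unique(key, axis=0, return_inverse=True)
    if len(uniq) == len(xy):
        return xy, values
    sums = np.zeros(len(uniq))
    counts = np.zeros(len(uniq))
    np.add.at(sums, inverse, values)
    np.add.at(counts, inverse, 1.0)
    return uniq, sums / counts


def empirical_variogram(xy: np.ndarray, values: np.ndarray, n_lags: int = 15,
                        max_lag: float | None = None):
    """Binned empirical semivariance 0.5 * mean (z_i - z_j)^2 per lag bin."""
    n = len(xy)
    idx_i, idx_j = np.triu_indices(n, k=1)
    d = np.hypot(*(xy[idx_i] - xy[idx_j]).T)
    sq = 0.5 * (values[idx_i] - values[idx_j]) ** 2
    if max_lag is None:
        max_lag = 0.5 * d.max() if d.size else 1.0
    keep = d <= max_lag
    d, sq = d[keep], sq[keep]
    edges = np.linspace(0.0, max_lag, n_lags + 1)
    which = np.clip(np.digitize(d, edges) - 1, 0, n_lags - 1)
    lags, gammas, counts = [], [], []
    for b in range(n_lags):
        m = which == b
        if m.sum() > 0:
            lags.append(d[m].mean())
            gammas.append(sq[m].mean())
            counts.append(m.sum())
    return np.array(lags), np.array(gammas), np.array(counts)


def fit_variogram(xy: np.ndarray, values: np.ndarray,
                  spec: VariogramSpec | None = None) -> VariogramSpec:
    """Fit (nugget, partial sill, range) by count-weighted least squares."""
    spec = spec or VariogramSpec()
    if spec.fit_mode == "fixed":
        return spec
    lags, gammas, counts = empirical_variogram(xy, values)
    if len(lags) < 3 or np.allclose(gammas, 0.0):
        # flat field: degenerate variogram, pure nugget-free constant model
        return VariogramSpec(model=spec.model, nugget=0.0,
                             sill=max(float(np.var(values)), 1e-12),
                             range=max(float(lags.max()) if len(lags) else 1.0, 1e-9),
                             fit_mode="fixed")
    var0 = max(float(np.var(values)), 1e-12)
    rng0 = float(lags.max()) * 0.6
    mdl = _MODELS[spec.model]
    w = np.sqrt(counts)

    def resid(p):
        return w * (mdl(lags, p[0], p[1], p[2]) - gammas)

    sol = least_squares(
        resid,
        x0=[0.0, var0, rng0],
        bounds=([0.0, 1e-12, 1e-9 * rng0 + 1e-12], [var0 * 2, var0 * 10, rng0 * 10]),
    )
    nugget, psill, rng = sol.x
    return VariogramSpec(model=spec.model, nugget=float(nugget), sill=float(psill),
                         range=float(rng), fit_mode="fixed")


def _idw(xy, values, targets, power: float = 2.0):
    tree = cKDTree(xy)
    d, idx = tree.query(targets, k=min(len(xy), 12))
    d = np.atleast_2d(d)
    idx = np.atleast_2d(idx)
    w = 1.0 / np.maximum(d, 1e-9) ** power
    w /= w.sum(axis=1, keepdims=True)
    pred = (w * values[idx]).sum(axis=1)
    exact = d[:, 0] < 1e-9
    pred[exact] = values[idx[exact, 0]]
    return pred


def krige_field(
    sample_xy: np.ndarray,
    sample_values: np.ndarray,
    target_xy: np.ndarray,
    spec: VariogramSpec | None = None,
    max_neighbors: int = 48,
    clamp_to_range: bool = True,
) -> KrigingResult:
    """Ordinary kriging of scattered samples onto target points.

    Requires >= 10 samples. Duplicated coordinates are averaged first.
    Falls back to inverse-distance weighting (with a logged warning) if
    the kriging system is singular.
    """
    sample_xy = np.asarray(sample_xy, dtype=float)
    sample_values = np.asarray(sample_values, dtype=float)
    target_xy = np.asarray(target_xy, dtype=float)
    if len(sample_xy) < 10:
        raise ValueError("kriging requires at least 10 sample points")
    sample_xy, sample_values = _average_duplicates(sample_xy, sample_values)

    lo, hi = float(sample_values.min()), float(sample_values.max())
    if np.isclose(lo, hi):
        pred = np.full(len(target_xy), lo)
        return KrigingResult(pred, np.zeros(len(target_xy)),
                             VariogramSpec(nugget=0.0, sill=0.0, range=1.0, fit_mode="fixed"))

    vspec = fit_variogram(sample_xy, sample_values, spec)
    tree = cKDTree(sample_xy)
    k = min(max_neighbors, len(sample_xy))
    dists, neighbors = tree.query(target_xy, k=k)
    dists = np.atleast_2d(dists)
    neighbors = np.atleast_2d(neighbors)

    pred = np.empty(len(target_xy))
    sterr = np.empty(len(target_xy))
    fell_back = False
    for i in range(len(target_xy)):
        nb = neighbors[i]
        pts = sample_xy[nb]
        vals = sample_values[nb]
        # OK system in semivariance form with a Lagrange multiplier
        h = np.hypot(pts[:, None, 0] - pts[None, :, 0], pts[:, None, 1] - pts[None, :, 1])
        gam = vspec.gamma(h)
        np.fill_diagonal(gam, 0.0)
        a = np.empty((k + 1, k + 1))
        a[:k, :k] = gam
        a[k, :] = 1.0
        a[:, k] = 1.0
        a[k, k] = 0.0
        g0 = vspec.gamma(dists[i])
        g0 = np.where(dists[i] < 1e-9, 0.0, g0)
        b = np.append(g0, 1.0)
        try:
            sol = np.linalg.solve(a, b)
        except np.linalg.LinAlgError:
            fell_back = True
            break
        w, mu = sol[:k], sol[k]
        pred[i] = w @ vals
        var = max(float(w @ g0 + mu), 0.0)
        sterr[i] = np.sqrt(var)

    if fell_back:
        warnings.warn("singular kriging system; falling back to inverse-distance weighting")
        pred = _idw(sample_xy, sample_values, target_xy)
        sterr = np.full(len(target_xy), np.nan)
        return KrigingResult(pred, sterr, vspec, method="idw_fallback")

    n_clamped = 0
    if clamp_to_range:
        out = (pred < lo) | (pred > hi)
        n_clamped = int(out.sum())
        if n_clamped:
            log.info("kriging: clamped %d of %d predictions to the data range [%g, %g]",
                     n_clamped, len(pred), lo, hi)
            pred = np.clip(pred, lo, hi)
    return KrigingResult(pred, sterr, vspec, n_clamped=n_clamped)
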