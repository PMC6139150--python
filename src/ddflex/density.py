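"""Model-induced maps and the simultaneous kernel-width / threshold match.

The model-induced map is the convolution of the (coarse-grained) atomic model
with an isotropic 3D Gaussian of standard deviation ``sigma``.  The free
parameters ``sigma`` (kernel width), ``T`` (density threshold) and ``a``
(intensity scale) are determined so that three summary statistics of the
thresholded model map match those of the experimental map: the volume ``V``
(number of above-threshold voxels), the integral ``I`` of the
threshold-subtracted density, and the 95% quantile ``Q`` of the
threshold-subtracted density.  Matching the volume fixes ``T`` as an order
statistic of the map values; matching ``I/Q`` (a scale-free residual) fixes
``sigma`` by Newton iteration; ``a = I1/I2`` then matches the intensities.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .grid_io import DensityMap


class ProjectionError(ValueError):
    """Atom falls outside the (padded) target grid."""


class EmptyMapError(ValueError):
    """The experimental map has no positive density."""


class ConvergenceError(RuntimeError):
    """The sigma/T matching iteration failed to converge."""


@dataclasses.dataclass
class MapSummary:
    """Volume / integral / quantile summary of a thresholded map.

    ``volume`` counts voxels strictly above the threshold; ``integral`` sums
    the threshold-subtracted density over them; ``quantile`` is the 95%
    empirical quantile (ascending order statistic at 1-based index
    ``ceil(0.95 V)``) of the threshold-subtracted values, ``None`` when the
    volume is zero.
    """

    volume: int
    integral: float
    quantile: float | None


@dataclasses.dataclass
class MapMatchParams:
    """Converged kernel width, threshold and scale, with solver diagnostics."""

    sigma: float
    threshold: float
    scale: float
    iterations: int
    residual: float


def project_model(positions: np.ndarray, weights: np.ndarray,
                  template: DensityMap, sigma: float,
                  truncate: float = 4.0) -> DensityMap:
    """Gaussian-kernel projection of weighted points onto the template grid.

    Each point contributes ``w * (2 pi sigma^2)^{-3/2} exp(-|x-r|^2 / 2 sigma^2)``
    sampled at voxel centres and truncated beyond ``truncate * sigma`` per axis,
    so the map integral (sum times voxel volume) equals the total weight up to
    truncation/sampling error.

    Raises
    ------
    ProjectionError
        If a point lies more than ``truncate * sigma`` outside the grid.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    positions = np.asarray(positions, dtype=float)
    weights = np.asarray(weights, dtype=float)
    nz, ny, nx = template.values.shape
    dims = np.array([nx, ny, nz])
    vox = template.voxel_size
    origin = template.origin
    out = np.zeros_like(template.values)
    norm = (2.0 * math.pi * sigma * sigma) ** -1.5
    reach = truncate * sigma
    # per-axis voxel-centre coordinate arrays
    axes = [origin[d] + vox[d] * np.arange(dims[d]) for d in range(3)]
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    for i, (r, w) in enumerate(zip(positions, weights)):
        lo = np.ceil((r - reach - origin) / vox).astype(int)
        hi = np.floor((r + reach - origin) / vox).astype(int)
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, dims - 1)
        if np.any(lo > hi):
            raise ProjectionError(
                f"atom {i} at {tuple(np.round(r, 2))} lies outside the padded grid")
        g1d = [np.exp(-((axes[d][lo[d]:hi[d] + 1] - r[d]) ** 2) * inv2s2)
               for d in range(3)]
        out[lo[2]:hi[2] + 1, lo[1]:hi[1] + 1, lo[0]:hi[0] + 1] += (
            (w * norm)
            * g1d[2][:, None, None] * g1d[1][None, :, None] * g1d[0][None, None, :])
    return template.like(out)


def _quantile_above(values_minus_t: np.ndarray) -> float:
    """95% ascending order statistic (1-based index ceil(0.95 V))."""
    v = values_minus_t.size
    idx = max(int(math.ceil(0.95 * v)), 1) - 1
    return float(np.partition(values_minus_t, idx)[idx])


def map_summary(dmap: DensityMap, threshold: float) -> MapSummary:
    """Summaries V, I, Q of the map thresholded (subtract-and-clip) at ``threshold``."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    above = dmap.values[dmap.values > threshold] - threshold
    volume = int(above.size)
    if volume == 0:
        return MapSummary(0, 0.0, None)
    return MapSummary(volume, float(above.sum()), _quantile_above(above))


def em_summary(em_map: DensityMap) -> MapSummary:
    """Summaries of an experimental map already background-thresholded.

    The map is expected to contain the subtract-and-clip result, so the
    effective threshold is zero.
    """
    summary = map_summary(em_map, 0.0)
    if summary.volume == 0:
        raise EmptyMapError("empty EM map: no voxel above zero")
    return summary


def threshold_for_volume(dmap: DensityMap, v1: int) -> float:
    """Threshold such that (up to ties) exactly ``v1`` voxels exceed it.

    Returns the ``(N - v1)``-th ascending order statistic of the map values.
    With tied values the realised above-threshold count can deviate from
    ``v1``.
    """
    n = dmap.n_voxels
    if not 0 < v1 < n:
        raise ValueError(f"volume must be in (0, {n}), got {v1}")
    flat = dmap.values.ravel()
    idx = n - v1 - 1  # 0-based position of the 1-based (N - v1)-th value
    return float(np.partition(flat, idx)[idx])


def _iq_ratio(g: np.ndarray, threshold: float) -> float:
    above = g[g > threshold] - threshold
    if above.size == 0:
        return 0.0
    return float(above.sum()) / _quantile_above(above)


def solve_sigma_T(em_map: DensityMap, positions: np.ndarray,
                  weights: np.ndarray, sigma0: float,
                  tol_sigma: float = 1e-3, max_iter: int = 50,
                  rel_tol_d: float = 1e-6,
                  return_map: bool = False):
    """Solve the three matching equations for sigma, T and the scale a.

    Alternates (i) rebuilding the model-induced map at the current ``sigma``
    and setting ``T`` to the order statistic that matches the experimental
    volume, with (ii) one Newton-Raphson step on ``sigma`` for the residual
    ``D = I2/Q2 - I1/Q1`` (central finite-difference derivative at fixed T,
    step damped to half of sigma).  On convergence ``a = I1/I2``.

    Parameters
    ----------
    sigma0 : float
        Initial kernel width; a natural choice is R / (2 sqrt(3)) for a map of
        nominal resolution R.
    return_map : bool
        Also return the final model-induced map (unthresholded), saving a
        re-projection in callers that need it.

    Raises
    ------
    ConvergenceError
        If tolerances are not met within ``max_iter`` iterations, or sigma is
        driven out of the meaningful range for the grid.
    """
    if sigma0 <= 0:
        raise ValueError("sigma0 must be positive")
    es = em_summary(em_map)
    ratio1 = es.integral / es.quantile
    tol_d = rel_tol_d * ratio1
    sigma_min = 0.25 * float(np.min(em_map.voxel_size))
    extent = float(np.max(em_map.voxel_size * em_map.shape_xyz))
    sigma = float(sigma0)
    lo = hi = None  # bracket: D(lo) < 0 < D(hi)
    d_resid = np.inf
    d_history: list[float] = []
    for it in range(1, max_iter + 1):
        gmap = project_model(positions, weights, em_map, sigma)
        threshold = threshold_for_volume(gmap, es.volume)
        d_resid = _iq_ratio(gmap.values, threshold) - ratio1
        converged = abs(d_resid) < tol_d
        if not converged:
            # one Newton-Raphson step on sigma; the central-difference
            # derivative re-solves the volume-matching threshold at
            # sigma +/- h so it tracks the composed residual D(sigma, T(sigma))
            # (the fixed-T slope is about twice the true one, which would
            # degrade Newton to linear convergence)
            h = max(0.01 * sigma, 0.02)
            g_plus = project_model(positions, weights, em_map, sigma + h)
            g_minus = project_model(positions, weights, em_map, sigma - h)
            d_plus = _iq_ratio(g_plus.values,
                               threshold_for_volume(g_plus, es.volume))
            d_minus = _iq_ratio(g_minus.values,
                                threshold_for_volume(g_minus, es.volume))
            slope = (d_plus - d_minus) / (2.0 * h)
            if slope == 0.0:
                raise ConvergenceError(
                    f"flat residual at sigma={sigma:.4g} (D={d_resid:.4g})")
            dsigma = float(np.clip(-d_resid / slope, -0.5 * sigma, 0.5 * sigma))
            converged = abs(d_resid) < tol_d and abs(dsigma) < tol_sigma
        if converged:
            scale = es.integral / float(
                (gmap.values[gmap.values > threshold] - threshold).sum())
            params = MapMatchParams(sigma, threshold, scale, it, d_resid)
            return (params, gmap) if return_map else params
        # maintain a sign bracket: the quantile Q2 is an order statistic, so D
        # can jump across zero; once the bracket is narrower than tol_sigma the
        # residual has reached its discreteness floor and sigma is converged
        if d_resid < 0:
            lo = sigma
        else:
            hi = sigma
        if lo is not None and hi is not None:
            if abs(hi - lo) < tol_sigma:
                sigma = 0.5 * (lo + hi)
                gmap = project_model(positions, weights, em_map, sigma)
                threshold = threshold_for_volume(gmap, es.volume)
                above = gmap.values[gmap.values > threshold] - threshold
                d_resid = float(above.sum()) / _quantile_above(above) - ratio1
                scale = es.integral / float(above.sum())
                params = MapMatchParams(sigma, threshold, scale, it + 1, d_resid)
                return (params, gmap) if return_map else params
            # safeguarded step: keep the in-bracket Newton proposal while the
            # residual is actually shrinking; once it stalls (Newton hopping
            # across the jump), bisection halves the bracket instead
            proposal = sigma + dsigma
            lo_, hi_ = min(lo, hi), max(lo, hi)
            stalled = (len(d_history) >= 2
                       and abs(d_resid) > 0.5 * d_history[-2])
            if lo_ < proposal < hi_ and not stalled:
                sigma = proposal
            else:
                sigma = 0.5 * (lo + hi)
        else:
            sigma += dsigma
        d_history.append(abs(d_resid))
        if sigma < sigma_min or sigma > extent:
            raise ConvergenceError(
                f"sigma driven out of range ({sigma:.4g} A) at iteration {it}")
    raise ConvergenceError(
        f"no convergence in {max_iter} iterations (last D={d_resid:.4g})")
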