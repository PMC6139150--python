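"""Online overfitting guard based on the saturation of the overlap curve.

The overlap series y(t) along a refinement trajectory is fitted at every step
with the saturating exponential

    y(t) = b - c * exp(-k t),

by variable projection: for each trial decay rate k the linear parameters
(b, c) have a closed-form least-squares solution on the basis {1, e^{-kt}},
and the profiled residual sum of squares is minimised over k on a log grid
refined by bounded 1D search.  The warning time t1 and stopping time t2 are
the steps at which the fitted curve has covered fractions alpha1 / alpha2 of
its total rise:

    t_i = (1/k) ln(1 / (1 - alpha_i)).

The refinement runs while t2 exceeds the current step; frames past t1 are
flagged as probable overfitting.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.optimize import minimize_scalar

DEFAULT_ALPHA1 = 0.9
DEFAULT_ALPHA2 = 0.99
DEFAULT_MIN_POINTS = 10
_LOGK_LO, _LOGK_HI = -8.0, 2.0
_GRID_SIZE = 50


@dataclasses.dataclass
class RegressionFit:
    """Fitted parameters of y(t) = b - c exp(-k t)."""

    b: float
    c: float
    k: float
    rss: float
    n_points: int


@dataclasses.dataclass
class StoppingDecision:
    t1: int | None
    t2: int | None
    stop_now: bool
    alpha1: float
    alpha2: float
    fit: RegressionFit | None


def _profile(logk: float, t: np.ndarray, y: np.ndarray):
    """Closed-form (b, c) and RSS for a trial decay rate k = exp(logk)."""
    k = math.exp(logk)
    basis = np.column_stack([np.ones_like(t), np.exp(-k * t)])
    coef, _, _, _ = np.linalg.lstsq(basis, y, rcond=None)
    resid = y - basis @ coef
    return float(resid @ resid), float(coef[0]), float(-coef[1]), k


def fit_exponential(times, overlaps,
                    min_points: int = DEFAULT_MIN_POINTS) -> RegressionFit | None:
    """Variable-projection fit of the saturating exponential.

    Returns ``None`` (fit rejected) for short or constant series, when the
    profiled optimum sits at the edge of the search bracket
    ``log k in [-8, 2]``, or when the fitted amplitude c is not positive.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(overlaps, dtype=float)
    if t.size < min_points or np.ptp(y) == 0.0:
        return None
    grid = np.linspace(_LOGK_LO, _LOGK_HI, _GRID_SIZE)
    rss = np.array([_profile(lk, t, y)[0] for lk in grid])
    best = int(np.argmin(rss))
    if best in (0, _GRID_SIZE - 1):
        return None
    res = minimize_scalar(lambda lk: _profile(lk, t, y)[0],
                          bounds=(grid[best - 1], grid[best + 1]),
                          method="bounded",
                          options={"xatol": 1e-10})
    rss_opt, b, c, k = _profile(float(res.x), t, y)
    if c <= 0 or not np.isfinite(rss_opt):
        return None
    return RegressionFit(b, c, k, rss_opt, int(t.size))


def warning_stopping_times(k: float, alpha1: float = DEFAULT_ALPHA1,
                           alpha2: float = DEFAULT_ALPHA2) -> tuple[float, float]:
    """Times at which the fitted curve covers fractions alpha1/alpha2 of its rise."""
    if k <= 0:
        raise ValueError("decay rate k must be positive")
    if not 0 < alpha1 < alpha2 < 1:
        raise ValueError("need 0 < alpha1 < alpha2 < 1")
    t1 = math.log(1.0 / (1.0 - alpha1)) / k
    t2 = math.log(1.0 / (1.0 - alpha2)) / k
    return t1, t2


class StoppingMonitor:
    """Accumulates the overlap series and re-fits the regression every step."""

    def __init__(self, alpha1: float = DEFAULT_ALPHA1,
                 alpha2: float = DEFAULT_ALPHA2,
                 min_points: int = DEFAULT_MIN_POINTS):
        self.alpha1 = alpha1
        self.alpha2 = alpha2
        self.min_points = min_points
        self.times: list[int] = []
        self.overlaps: list[float] = []
        self.frozen_t1: int | None = None
        self.stopped_at: int | None = None

    def update(self, t: int, overlap: float) -> StoppingDecision:
        """Record one (step, overlap) point and decide whether to stop.

        Stops when the current stopping-time estimate t2 (rounded to the
        nearest step) no longer exceeds the current step.  On stop, the
        current t1 estimate is frozen as the reported warning time.
        """
        self.times.append(int(t))
        self.overlaps.append(float(overlap))
        fit = fit_exponential(self.times, self.overlaps, self.min_points)
        if fit is None:
            return StoppingDecision(None, None, False, self.alpha1, self.alpha2, None)
        t1f, t2f = warning_stopping_times(fit.k, self.alpha1, self.alpha2)
        t1, t2 = round(t1f), round(t2f)
        stop_now = t2 <= t
        if stop_now and self.stopped_at is None:
            self.stopped_at = int(t)
            self.frozen_t1 = int(t1)
        return StoppingDecision(int(t1), int(t2), stop_now,
                                self.alpha1, self.alpha2, fit)

    def flag_overfit_frames(self, frame_steps) -> list[bool]:
        """Mark saved frames recorded after the frozen warning time."""
        if self.frozen_t1 is None:
            return [False] * len(frame_steps)
        return [s > self.frozen_t1 for s in frame_steps]

    def report(self) -> dict:
        """JSON-ready stopping report."""
        fit = fit_exponential(self.times, self.overlaps, self.min_points)
        out = {"t1": self.frozen_t1, "t2": None, "b": None, "c": None,
               "k": None, "n_points": len(self.times),
               "stopped_at": self.stopped_at}
        if fit is not None:
            t1f, t2f = warning_stopping_times(fit.k, self.alpha1, self.alpha2)
            out.update(b=fit.b, c=fit.c, k=fit.k, t2=round(t2f))
            if out["t1"] is None:
                out["t1"] = round(t1f)
        return out
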