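"""Adaptive damper cutoff distance.

The collective damping constant of the network scales as ``d_cut^{5/2}``
(dampers of length r have strength 1/sqrt(r), and the number with length in
[r, r+dr] grows like r^2 dr), so keeping the RMS velocity v of the structure
constant under a slowly varying collective force calls for the update

    d_cut(t+1) = d_cut(t) * rho^{2/5},      rho = v(t) / v(t-1).

The decrease is allowed until d_cut reaches the floor ``max(7 A, 2 sigma)``,
which preserves a minimum of connectivity; growth is capped at the initial
value.
"""

from __future__ import annotations

import dataclasses
import logging

logger = logging.getLogger(__name__)

DEFAULT_D_INIT = 14.0
FLOOR_ABS = 7.0


def cutoff_floor(sigma: float, floor_override: float | None = None) -> float:
    if floor_override is not None:
        return float(floor_override)
    return max(FLOOR_ABS, 2.0 * sigma)


@dataclasses.dataclass
class CutoffState:
    d_cut: float
    d_init: float = DEFAULT_D_INIT
    floor_override: float | None = None
    at_floor: bool = False


def update_dcut(state: CutoffState, v_prev: float, v_curr: float,
                sigma: float) -> CutoffState:
    """One cutoff update from the velocity ratio rho = v_curr / v_prev.

    ``rho < 1`` shrinks the cutoff by ``rho^{2/5}``; the result is clamped to
    ``[max(7, 2 sigma), d_init]``.  A vanishing ``v_prev`` leaves the cutoff
    unchanged.
    """
    if v_prev <= 0:
        logger.info("previous RMS velocity is zero: d_cut left unchanged")
        return dataclasses.replace(state)
    rho = v_curr / v_prev
    d_new = state.d_cut * rho ** 0.4
    floor = cutoff_floor(sigma, state.floor_override)
    clamped = min(max(d_new, floor), state.d_init)
    return dataclasses.replace(state, d_cut=clamped,
                               at_floor=(d_new <= floor))
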