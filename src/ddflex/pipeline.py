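"""End-to-end refinement loop with logging, trajectory output and reports.

Each step re-solves the kernel width / threshold / scale of the model-induced
map (warm-started from the previous step), builds the difference map and the
map force, assembles the damper network at the current cutoff, solves the
constrained overdamped system, updates positions, adapts the cutoff from the
RMS-velocity ratio, and feeds the overlap to the stopping monitor.  The run
ends at the estimated stopping time t2 or at ``max_steps``.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import subprocess
from pathlib import Path

import numpy as np
import pandas as pd

from . import cutoff as cutoff_mod
from . import density, engine, grid_io, stopping

logger = logging.getLogger(__name__)

LOG_COLUMNS = ["t", "overlap", "v", "d_cut", "sigma", "T", "a",
               "t1_est", "t2_est"]


@dataclasses.dataclass
class RefinementConfig:
    """Tunable parameters of a refinement run (distances in Angstrom)."""

    resolution: float
    sigma0: float | None = None          # default R / (2 sqrt(3))
    alpha1: float = stopping.DEFAULT_ALPHA1
    alpha2: float = stopping.DEFAULT_ALPHA2
    d_init: float = cutoff_mod.DEFAULT_D_INIT
    floor_override: float | None = None
    max_steps: int = 500
    save_every: int = 5
    delta_max: float = 0.3
    c0: float = 1.0
    epsilon_factor: float = 0.01         # V = epsilon_factor * c0 * I
    dt_cap_factor: float = 20.0          # cap dt at this multiple of the first dt
    sse_mode: str = "none"               # none | endpoints | rigidify
    min_points: int = stopping.DEFAULT_MIN_POINTS
    seed: int = 0
    sidechain_command: str | None = None  # optional external hook per saved frame

    def initial_sigma(self) -> float:
        if self.sigma0 is not None:
            return float(self.sigma0)
        return self.resolution / (2.0 * math.sqrt(3.0))


@dataclasses.dataclass
class RefinementResult:
    model: engine.CoarseModel            # final conformation
    frames: list                         # (step, positions) saved frames
    frame_flags: list                    # per-frame possible-overfitting flags
    log: pd.DataFrame
    report: dict


def _sidechain_hook(command: str, frame_path: str) -> None:
    """Run a user-supplied side-chain optimisation command on a saved frame."""
    try:
        subprocess.run(command.format(pdb=frame_path), shell=True, check=True)
    except subprocess.CalledProcessError as exc:
        logger.warning("side-chain hook failed: %s", exc)


def run_refinement(model: grid_io.AtomicModel, em_map: grid_io.DensityMap,
                   config: RefinementConfig,
                   user_constraints=None,
                   target: grid_io.AtomicModel | None = None) -> RefinementResult:
    """Refine ``model`` against ``em_map``.

    ``user_constraints`` is an optional list of
    ``(chain, resid, atom, chain, resid, atom[, dist])`` entries.  If a
    ``target`` model is given (synthetic validation), a backbone-RMSD-to-target
    column is added to the log.

    Raises
    ------
    RuntimeError
        On diverging RMS velocity (>10x initial) or non-finite coordinates.
    """
    em = em_map.like(np.clip(em_map.values, 0.0, None))
    cm = engine.coarse_grain(model)
    target_cm = engine.coarse_grain(target) if target is not None else None

    constraints = engine.ConstraintSet.from_pairs(cm.bonded_pairs, cm.positions)
    if config.sse_mode != "none":
        constraints = constraints.merge(
            engine.build_sse_constraints(model, cm, config.sse_mode))
    if user_constraints:
        constraints = constraints.merge(
            engine.resolve_constraint_list(user_constraints, cm))

    epsilon = config.epsilon_factor * config.c0
    sigma = config.initial_sigma()
    dcut_state = cutoff_mod.CutoffState(config.d_init, config.d_init,
                                        config.floor_override)
    monitor = stopping.StoppingMonitor(config.alpha1, config.alpha2,
                                       config.min_points)
    rows = []
    frames = []
    v_prev = None
    v_first = None
    dt_first = None
    rmsd_col = []

    for t in range(1, config.max_steps + 1):
        params, gmap = density.solve_sigma_T(em, cm.positions, cm.weights,
                                             sigma0=sigma, return_map=True)
        sigma = params.sigma
        model_thr = np.clip(gmap.values - params.threshold, 0.0, None)
        diff = em.like(em.values - params.scale * model_thr)
        forces = engine.map_force(cm.positions, diff)
        dampers = engine.assemble_dampers(cm.positions, dcut_state.d_cut,
                                          config.c0,
                                          exclude_pairs=constraints.pairs)
        dt_cap = (config.dt_cap_factor * dt_first) if dt_first else None
        result = engine.step(cm.positions, dampers, constraints, forces,
                             epsilon, config.delta_max, dt_max=dt_cap)
        if not np.all(np.isfinite(result.positions)):
            raise RuntimeError(f"non-finite coordinates at step {t}")
        cm.positions = result.positions
        if dt_first is None and result.dt > 0:
            dt_first = result.dt

        v = engine.rms_velocity(result.velocities)
        if v_first is None:
            v_first = v
        elif v_first > 0 and v > 10.0 * v_first:
            raise RuntimeError(
                f"diverging dynamics at step {t}: v={v:.3g} vs initial {v_first:.3g}")
        overlap = engine.overlap_percent(em, gmap, params.threshold)

        if v_prev is not None:
            dcut_state = cutoff_mod.update_dcut(dcut_state, v_prev, v, sigma)
        v_prev = v
        decision = monitor.update(t, overlap)
        rows.append([t, overlap, v, dcut_state.d_cut, sigma, params.threshold,
                     params.scale, decision.t1, decision.t2])
        if target_cm is not None:
            rmsd_col.append(engine.backbone_rmsd(cm, target_cm))
        if t % config.save_every == 0 or decision.stop_now or t == config.max_steps:
            frames.append((t, cm.positions.copy()))
        if decision.stop_now:
            logger.info("stopping criterion fired at step %d (t1=%s, t2=%s)",
                        t, decision.t1, decision.t2)
            break

    log = pd.DataFrame(rows, columns=LOG_COLUMNS)
    if target_cm is not None:
        log["rmsd_to_target"] = rmsd_col
    report = monitor.report()
    flags = monitor.flag_overfit_frames([s for s, _ in frames])
    return RefinementResult(cm, frames, flags, log, report)


def save_outputs(result: RefinementResult, prefix: str,
                 sidechain_command: str | None = None) -> dict:
    """Write trajectory PDB, CSV log and JSON stopping report.

    Returns the paths written.  If a side-chain command is configured it is
    invoked once on the written trajectory file (external post-processing
    hook; never required).
    """
    prefix_path = Path(prefix)
    prefix_path.parent.mkdir(parents=True, exist_ok=True)
    models = []
    base = result.model
    for _, positions in result.frames:
        frame = base.copy()
        frame.positions = positions
        models.append(frame.to_atomic_model())
    traj_path = f"{prefix}_trajectory.pdb"
    log_path = f"{prefix}_log.csv"
    report_path = f"{prefix}_stopping.json"
    grid_io.write_trajectory(models, traj_path)
    result.log.to_csv(log_path, index=False)
    report = dict(result.report)
    report["frames"] = [
        {"step": s, "possible_overfitting": bool(f)}
        for (s, _), f in zip(result.frames, result.frame_flags)]
    grid_io.write_stopping_report(report, report_path)
    if sidechain_command:
        _sidechain_hook(sidechain_command, traj_path)
    return {"trajectory": traj_path, "log": log_path, "report": report_path}


def analyze_run(log_path, alpha1: float = stopping.DEFAULT_ALPHA1,
                alpha2: float = stopping.DEFAULT_ALPHA2) -> dict:
    """Re-derive the overlap/RMSD tables and t1/t2 annotations from a run log."""
    log = pd.read_csv(log_path)
    if log.empty:
        raise ValueError(f"empty run log: {log_path}")
    missing = [c for c in ("t", "overlap") if c not in log.columns]
    if missing:
        raise ValueError(f"run log lacks columns {missing}")
    fit = stopping.fit_exponential(log["t"], log["overlap"])
    t1 = t2 = None
    if fit is not None:
        t1f, t2f = stopping.warning_stopping_times(fit.k, alpha1, alpha2)
        t1, t2 = round(t1f), round(t2f)
    out = {
        "n_steps": int(log["t"].iloc[-1]),
        "overlap_vs_t": log[["t", "overlap"]],
        "t1": t1,
        "t2": t2,
        "overlap_initial": float(log["overlap"].iloc[0]),
        "overlap_final": float(log["overlap"].iloc[-1]),
    }
    if "rmsd_to_target" in log.columns:
        out["rmsd_vs_t"] = log[["t", "rmsd_to_target"]]
        out["rmsd_final"] = float(log["rmsd_to_target"].iloc[-1])
    return out
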