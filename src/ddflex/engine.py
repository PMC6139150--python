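"""Coarse-grained overdamped dynamics with dampers and distance constraints.

The model is reduced to pseudo-atoms (backbone heavy atoms N, CA, C, O plus
one side-chain centroid per residue), moving in Cartesian coordinates
(``M = 3A`` degrees of freedom).  Motion is first order: at every step the
velocities solve

    (B + V) q_dot - J^T h = Q,      J q_dot = 0,

where ``B`` is the assembled damper matrix (pairwise dashpots acting along the
connecting line, strength ``c0 / sqrt(r)`` for a damper of rest length ``r``),
``V = eps * I`` a background viscosity, ``J`` the Jacobian of the distance
constraints (Wilson matrix, which in Cartesian coordinates reduces to position
differences), ``h`` the Lagrange multipliers and ``Q`` the map-derived force.
Covalent geometry is preserved by auto-generated distance constraints between
bonded and 1-3 backbone pseudo-atom pairs.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.ndimage import map_coordinates
from scipy.spatial import cKDTree

from .grid_io import AtomicModel, DensityMap

logger = logging.getLogger(__name__)

BACKBONE_NAMES = ("N", "CA", "C", "O")
SIDECHAIN_NAME = "SC"
_MIN_DAMPER_LENGTH = 0.1

_STD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


@dataclasses.dataclass
class CoarseModel:
    """Pseudo-atom model carrying the dynamics.

    Arrays are parallel over the ``A`` pseudo-atoms; ``bonded_pairs`` lists the
    covalent-geometry constraint pairs (indices into the pseudo-atom arrays)
    generated at coarse-graining time.
    """

    positions: np.ndarray        # (A, 3) Angstrom
    weights: np.ndarray          # (A,) amu
    chains: np.ndarray           # (A,) str
    resids: np.ndarray           # (A,) int
    resnames: np.ndarray         # (A,) str
    names: np.ndarray            # (A,) pseudo-atom role name: N/CA/C/O/SC
    bonded_pairs: np.ndarray     # (nb, 2) int

    @property
    def n_atoms(self) -> int:
        return int(len(self.positions))

    @property
    def n_coords(self) -> int:
        return 3 * self.n_atoms

    @property
    def backbone_mask(self) -> np.ndarray:
        return np.isin(self.names, BACKBONE_NAMES)

    def index_of(self, chain: str, resid: int, name: str) -> int:
        hits = np.flatnonzero((self.chains == chain) & (self.resids == resid)
                              & (self.names == name))
        if hits.size == 0:
            raise KeyError(f"no pseudo-atom {chain}/{resid}/{name}")
        return int(hits[0])

    def to_atomic_model(self) -> AtomicModel:
        """Pseudo-atom representation as an AtomicModel (for PDB output)."""
        import pandas as pd
        element = np.where(self.names == "N", "N",
                           np.where(self.names == "O", "O", "C"))
        atoms = pd.DataFrame({
            "chain": self.chains, "resid": self.resids,
            "resname": self.resnames, "name": self.names,
            "element": element, "mass": self.weights,
            "x": self.positions[:, 0], "y": self.positions[:, 1],
            "z": self.positions[:, 2],
            "occ": 1.0, "bfac": 0.0,
        })
        return AtomicModel(atoms)

    def copy(self) -> "CoarseModel":
        return dataclasses.replace(self, positions=self.positions.copy())


@dataclasses.dataclass
class ConstraintSet:
    """Pairwise distance constraints f = 0.5 |r_a - r_b|^2 - 0.5 d^2."""

    pairs: np.ndarray    # (K, 2) int
    targets: np.ndarray  # (K,) Angstrom

    @classmethod
    def empty(cls) -> "ConstraintSet":
        return cls(np.zeros((0, 2), dtype=int), np.zeros(0))

    @classmethod
    def from_pairs(cls, pairs, positions: np.ndarray,
                   targets=None) -> "ConstraintSet":
        pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
        if targets is None:
            d = positions[pairs[:, 0]] - positions[pairs[:, 1]]
            targets = np.linalg.norm(d, axis=1)
        return cls(pairs, np.asarray(targets, dtype=float))

    @property
    def n_constraints(self) -> int:
        return int(len(self.pairs))

    def merge(self, other: "ConstraintSet") -> "ConstraintSet":
        """Concatenate, dropping duplicate pairs (keeping the first target)."""
        seen = {tuple(sorted(p)) for p in self.pairs.tolist()}
        keep = [i for i, p in enumerate(other.pairs.tolist())
                if tuple(sorted(p)) not in seen]
        return ConstraintSet(
            np.vstack([self.pairs, other.pairs[keep]]),
            np.concatenate([self.targets, other.targets[keep]]))

    def jacobian(self, positions: np.ndarray) -> sp.csr_matrix:
        """Wilson-matrix rows d f_alpha / d q_i = <r_a - r_b, ...> at ``positions``."""
        k = self.n_constraints
        m = 3 * len(positions)
        if k == 0:
            return sp.csr_matrix((0, m))
        a, b = self.pairs[:, 0], self.pairs[:, 1]
        d = positions[a] - positions[b]
        rows = np.repeat(np.arange(k), 6)
        cols = np.concatenate([(3 * a[:, None] + np.arange(3)),
                               (3 * b[:, None] + np.arange(3))], axis=1).ravel()
        vals = np.concatenate([d, -d], axis=1).ravel()
        return sp.csr_matrix((vals, (rows, cols)), shape=(k, m))

    def violations(self, positions: np.ndarray) -> np.ndarray:
        """Relative distance errors |d - d0| / d0 per constraint."""
        if self.n_constraints == 0:
            return np.zeros(0)
        d = np.linalg.norm(positions[self.pairs[:, 0]]
                           - positions[self.pairs[:, 1]], axis=1)
        return np.abs(d - self.targets) / self.targets


@dataclasses.dataclass
class DamperNetwork:
    """Pairwise dashpots within the cutoff, assembled into the matrix B."""

    pairs: np.ndarray       # (E, 2)
    rest_lengths: np.ndarray
    strengths: np.ndarray
    matrix: sp.csr_matrix   # (M, M) symmetric PSD

    @property
    def n_edges(self) -> int:
        return int(len(self.pairs))


def coarse_grain(model: AtomicModel) -> CoarseModel:
    """Reduce an atomic model to backbone pseudo-atoms plus side-chain centroids.

    Per residue the heavy atoms N, CA, C, O are kept (weights: their atomic
    masses) plus one mass-weighted side-chain centroid carrying the summed
    side-chain heavy-atom mass (glycine: none).  Covalent-geometry constraint
    pairs are generated between N-CA, CA-C, C-O, CA-SC, the 1-3 pair N-C, and
    across the peptide bond C-N(next) and CA-N(next).
    """
    pos, wts, chains, resids, resnames, names = [], [], [], [], [], []
    index = {}
    for chain, resid, resname, grp in model.residues():
        if resname not in _STD_RESIDUES:
            logger.warning("nonstandard residue %s %s%d: using available atoms",
                           resname, chain, resid)
        heavy = grp[grp["element"].str.upper() != "H"]
        for bb in BACKBONE_NAMES:
            row = heavy[heavy["name"] == bb]
            if row.empty:
                continue
            row = row.iloc[0]
            index[(chain, resid, bb)] = len(pos)
            pos.append([row.x, row.y, row.z])
            wts.append(row.mass)
            chains.append(chain); resids.append(resid)
            resnames.append(resname); names.append(bb)
        side = heavy[~heavy["name"].isin(BACKBONE_NAMES + ("OXT",))]
        if not side.empty:
            m = side["mass"].to_numpy()
            xyz = side[["x", "y", "z"]].to_numpy()
            index[(chain, resid, SIDECHAIN_NAME)] = len(pos)
            pos.append(list((m[:, None] * xyz).sum(axis=0) / m.sum()))
            wts.append(float(m.sum()))
            chains.append(chain); resids.append(resid)
            resnames.append(resname); names.append(SIDECHAIN_NAME)

    bonded = []

    def link(key1, key2):
        i, j = index.get(key1), index.get(key2)
        if i is not None and j is not None:
            bonded.append((i, j))

    residue_keys = []
    for chain, resid, _, _ in model.residues():
        if (chain, resid) not in residue_keys:
            residue_keys.append((chain, resid))
    for chain, resid in residue_keys:
        link((chain, resid, "N"), (chain, resid, "CA"))
        link((chain, resid, "CA"), (chain, resid, "C"))
        link((chain, resid, "C"), (chain, resid, "O"))
        link((chain, resid, "CA"), (chain, resid, SIDECHAIN_NAME))
        link((chain, resid, "N"), (chain, resid, "C"))          # 1-3 angle fix
    for (c1, r1), (c2, r2) in zip(residue_keys[:-1], residue_keys[1:]):
        if c1 == c2 and r2 == r1 + 1:
            link((c1, r1, "C"), (c2, r2, "N"))                  # peptide bond
            link((c1, r1, "CA"), (c2, r2, "N"))                 # 1-3 angle fix
    return CoarseModel(np.asarray(pos, dtype=float), np.asarray(wts),
                       np.asarray(chains), np.asarray(resids, dtype=int),
                       np.asarray(resnames), np.asarray(names),
                       np.asarray(bonded, dtype=int).reshape(-1, 2))


def assemble_dampers(positions: np.ndarray, d_cut: float, c0: float = 1.0,
                     exclude_pairs=None) -> DamperNetwork:
    """Create a damper for every non-excluded pair closer than ``d_cut``.

    A damper of rest length r has strength ``c0 / sqrt(r)`` (capped at
    ``c0 / sqrt(0.1)`` for clashing pairs) and contributes the line-projection
    block ``c * u u^T`` with the standard +/- pattern to the M x M matrix B.
    """
    if d_cut <= 0:
        raise ValueError("d_cut must be positive")
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    tree = cKDTree(positions)
    pairs = tree.query_pairs(d_cut, output_type="ndarray")
    if exclude_pairs is not None and len(exclude_pairs) and len(pairs):
        excl = {tuple(sorted(p)) for p in np.asarray(exclude_pairs).tolist()}
        keep = [k for k, p in enumerate(np.sort(pairs, axis=1).tolist())
                if tuple(p) not in excl]
        pairs = pairs[keep]
    m = 3 * n
    if len(pairs) == 0:
        return DamperNetwork(pairs.reshape(-1, 2), np.zeros(0), np.zeros(0),
                             sp.csr_matrix((m, m)))
    diff = positions[pairs[:, 0]] - positions[pairs[:, 1]]
    r = np.linalg.norm(diff, axis=1)
    clashing = r < _MIN_DAMPER_LENGTH
    if np.any(clashing):
        logger.warning("%d damper pairs closer than %.1f A: strength capped",
                       int(clashing.sum()), _MIN_DAMPER_LENGTH)
    strengths = c0 / np.sqrt(np.maximum(r, _MIN_DAMPER_LENGTH))
    u = diff / np.maximum(r, 1e-12)[:, None]
    blocks = strengths[:, None, None] * (u[:, :, None] * u[:, None, :])  # (E,3,3)
    e = len(pairs)
    a3 = 3 * pairs[:, 0]
    b3 = 3 * pairs[:, 1]
    off = np.arange(3)
    rows, cols, vals = [], [], []
    for base_r, base_c, sign in ((a3, a3, 1.0), (b3, b3, 1.0),
                                 (a3, b3, -1.0), (b3, a3, -1.0)):
        rr = (base_r[:, None, None] + off[None, :, None]).repeat(3, axis=2)
        cc = (base_c[:, None, None] + off[None, None, :]).repeat(3, axis=1)
        rows.append(rr.ravel())
        cols.append(cc.ravel())
        vals.append(sign * blocks.ravel())
    matrix = sp.csr_matrix((np.concatenate(vals),
                            (np.concatenate(rows), np.concatenate(cols))),
                           shape=(m, m))
    return DamperNetwork(pairs, r, strengths, matrix)


def aggregate_damper_strength(network: DamperNetwork) -> float:
    """Sum of all damper strengths (the collective constant C(d_cut))."""
    return float(network.strengths.sum())


def map_force(positions: np.ndarray, diff_map: DensityMap, gamma: float = 1.0,
              normalize: bool = True) -> np.ndarray:
    """Force pulling atoms up the gradient of the difference map.

    The gradient is computed by central differences on the grid and evaluated
    at atom positions by trilinear interpolation.  With ``normalize`` the
    force field is rescaled so the largest per-atom force norm is ``gamma``.
    Atoms outside the grid get zero force (with a warning).
    """
    positions = np.asarray(positions, dtype=float)
    vz, vy, vx = diff_map.voxel_size[2], diff_map.voxel_size[1], diff_map.voxel_size[0]
    gz, gy, gx = np.gradient(diff_map.values, vz, vy, vx)
    # grid coordinates (z, y, x) in voxel units
    coords = ((positions - diff_map.origin) / diff_map.voxel_size)[:, ::-1].T
    nzyx = np.array(diff_map.values.shape)
    inside = np.all((coords.T >= 0) & (coords.T <= nzyx - 1), axis=1)
    if not np.all(inside):
        logger.warning("%d atoms outside the map grid: zero force",
                       int((~inside).sum()))
    forces = np.zeros_like(positions)
    c_in = coords[:, inside]
    forces[inside, 0] = map_coordinates(gx, c_in, order=1, mode="nearest")
    forces[inside, 1] = map_coordinates(gy, c_in, order=1, mode="nearest")
    forces[inside, 2] = map_coordinates(gz, c_in, order=1, mode="nearest")
    if normalize:
        fmax = np.linalg.norm(forces, axis=1).max()
        if fmax > 0:
            forces *= gamma / fmax
    else:
        forces *= gamma
    return forces


@dataclasses.dataclass
class StepResult:
    positions: np.ndarray    # updated (A, 3)
    velocities: np.ndarray   # q_dot, (A, 3), pre-dt solve result
    multipliers: np.ndarray  # Lagrange multipliers h, (K,)
    dt: float


def solve_velocities(damping: sp.spmatrix, jacobian: sp.csr_matrix,
                     forces_flat: np.ndarray):
    """Solve the saddle (KKT) system for velocities and multipliers.

    The sparse saddle factorisation handles independent constraints; with
    redundant constraint rows (singular saddle matrix) the system is re-solved
    through the Schur complement of the always-definite damping block, with a
    least-squares solve for the multipliers.
    """
    m = forces_flat.size
    k = jacobian.shape[0]
    if k == 0:
        qdot = spla.spsolve(damping.tocsc(), forces_flat)
        return np.asarray(qdot), np.zeros(0)
    saddle = sp.bmat([[damping, -jacobian.T],
                      [jacobian, None]], format="csc")
    rhs = np.concatenate([forces_flat, np.zeros(k)])
    with warnings.catch_warnings():
        warnings.simplefilter("error", spla.MatrixRankWarning)
        try:
            sol = spla.spsolve(saddle, rhs)
            qnorm = np.linalg.norm(sol[:m])
            # accept only if the constraint-rate postcondition holds (a
            # near-singular saddle can factorise yet solve inaccurately)
            if (np.all(np.isfinite(sol))
                    and (k == 0 or qnorm == 0
                         or np.abs(jacobian @ sol[:m]).max() < 1e-9 * qnorm)):
                return sol[:m], sol[m:]
        except (RuntimeError, spla.MatrixRankWarning):
            pass
    logger.warning("singular saddle system (redundant constraints): "
                   "least-squares fallback")
    lu = spla.splu(damping.tocsc())
    x_f = lu.solve(forces_flat)
    x_j = lu.solve(jacobian.T.toarray())          # (m, k)
    schur = jacobian @ x_j                        # J A^-1 J^T, PSD, maybe singular
    h = np.linalg.lstsq(schur, -jacobian @ x_f, rcond=None)[0]
    qdot = x_f + x_j @ h
    return qdot, h


def _project_constraints(positions: np.ndarray, constraints: ConstraintSet,
                         tol: float = 1e-10, max_iter: int = 20) -> np.ndarray:
    """Gauss-Newton restoration of constrained distances.

    Solves ``J J^T lam = -C(q)`` (sparse SPD) and updates ``q += J^T lam``
    for the constraint functions ``C = 0.5 (|r_a - r_b|^2 - d0^2)``, iterating
    until the worst relative distance error drops below ``tol``.  Converges
    quadratically where SHAKE-style sweeps stall on stiff bond/angle triangles.
    """
    if constraints.n_constraints == 0:
        return positions
    pos = positions.copy()
    pairs, targets = constraints.pairs, constraints.targets
    for _ in range(max_iter):
        d = pos[pairs[:, 0]] - pos[pairs[:, 1]]
        dist = np.linalg.norm(d, axis=1)
        if (np.abs(dist - targets) / targets).max() < tol:
            break
        c = 0.5 * (dist ** 2 - targets ** 2)
        jac = constraints.jacobian(pos)
        gram = (jac @ jac.T).tocsc()
        gram += 1e-12 * sp.identity(gram.shape[0], format="csc")
        try:
            lam = spla.spsolve(gram, -c)
        except RuntimeError:
            lam = spla.lsqr(gram, -c)[0]
        pos = pos + (jac.T @ lam).reshape(pos.shape)
    return pos


def step(positions: np.ndarray, dampers: DamperNetwork,
         constraints: ConstraintSet, forces: np.ndarray,
         epsilon: float, delta_max: float = 0.3,
         dt_max: float | None = None,
         project_constraints: bool = True) -> StepResult:
    """One overdamped step: saddle solve, adaptive dt, position update.

    ``dt`` is chosen so the largest per-atom displacement equals ``delta_max``
    (optionally capped at ``dt_max``).  After the update, constrained
    distances are restored by a Gauss-Newton projection, which removes the
    second-order drift of the tangent motion.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive to make B + V definite")
    positions = np.asarray(positions, dtype=float)
    a = len(positions)
    m = 3 * a
    damping = (dampers.matrix + epsilon * sp.identity(m, format="csr")).tocsc()
    jac = constraints.jacobian(positions)
    qdot_flat, h = solve_velocities(damping, jac, np.asarray(forces).ravel())
    if constraints.n_constraints:
        rate = np.abs(jac @ qdot_flat).max()
        qnorm = np.linalg.norm(qdot_flat)
        if qnorm > 0 and rate > 1e-9 * qnorm:
            logger.warning("constraint-rate residual %.3g exceeds tolerance", rate)
    qdot = qdot_flat.reshape(a, 3)
    vmax = np.linalg.norm(qdot, axis=1).max()
    if vmax > 0:
        dt = delta_max / vmax
        if dt_max is not None:
            dt = min(dt, dt_max)
    else:
        dt = 0.0
    new_pos = positions + dt * qdot
    if project_constraints:
        new_pos = _project_constraints(new_pos, constraints)
    return StepResult(new_pos, qdot, h, dt)


def rms_velocity(velocities: np.ndarray) -> float:
    """RMS speed v with v^2 = (1/A) sum_i |r_dot_i|^2."""
    velocities = np.asarray(velocities, dtype=float).reshape(-1, 3)
    return float(np.sqrt((velocities ** 2).sum() / len(velocities)))


def overlap_percent(em_map: DensityMap, model_map: DensityMap,
                    threshold: float) -> float:
    """Coverage of the EM support by the model map's above-threshold region.

    Returns ``100 * |{EM > 0 and g > T}| / |{EM > 0}|``.
    """
    em_support = em_map.values > 0
    denom = int(em_support.sum())
    if denom == 0:
        raise EmptyMapErrorForOverlap("EM map has no positive support")
    num = int((em_support & (model_map.values > threshold)).sum())
    return 100.0 * num / denom


class EmptyMapErrorForOverlap(ValueError):
    pass


def kabsch_rotation(x: np.ndarray, y: np.ndarray):
    """Optimal rotation R and translation t minimising |R x + t - y|."""
    xc = x.mean(axis=0)
    yc = y.mean(axis=0)
    cov = (x - xc).T @ (y - yc)
    u, _, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, yc - rot @ xc


def rmsd(coords1: np.ndarray, coords2: np.ndarray,
         superpose: bool = False) -> float:
    """RMSD between two coordinate sets, optionally after rigid superposition."""
    coords1 = np.asarray(coords1, dtype=float)
    coords2 = np.asarray(coords2, dtype=float)
    if coords1.shape != coords2.shape:
        raise ValueError("coordinate sets differ in atom count")
    if superpose:
        rot, t = kabsch_rotation(coords1, coords2)
        coords1 = coords1 @ rot.T + t
    return float(np.sqrt(((coords1 - coords2) ** 2).sum(axis=1).mean()))


def backbone_rmsd(model1: CoarseModel, model2: CoarseModel,
                  superpose: bool = False) -> float:
    """RMSD over backbone pseudo-atoms (N, CA, C, O).

    ``superpose=False`` measures fitting accuracy in the shared map frame;
    ``superpose=True`` measures conformational difference after optimal rigid
    superposition.
    """
    m1 = model1.backbone_mask
    m2 = model2.backbone_mask
    if m1.sum() != m2.sum():
        raise ValueError("backbone atom counts differ")
    return rmsd(model1.positions[m1], model2.positions[m2], superpose)


def _sse_ranges(model: AtomicModel):
    for h in model.helices:
        yield h
    for strands in model.sheets:
        yield from strands


def build_sse_constraints(model: AtomicModel, cm: CoarseModel,
                          mode: str) -> ConstraintSet:
    """Secondary-structure distance constraints on the coarse model.

    mode "endpoints": for each pair of adjacent strands in a sheet, tie the
    terminal and penultimate CA pairs at both ends (4 constraints per adjacent
    strand pair), preserving the strand register while the sheet stays flexible.

    mode "rigidify": within every helix/strand, a triangulation that pins each
    pseudo-atom to its 3 predecessors in sequence order (the first three
    pairwise), i.e. 3n - 6 constraints per element; together with forward
    references every interior atom has >= 4 non-coplanar partners, keeping the
    element rigid.  Constraints duplicating covalent pairs are merged away by
    the caller, which can still leave the combined system redundant; the step
    solver handles that case.

    mode "none": empty set.
    """
    if mode == "none":
        return ConstraintSet.empty()
    pairs = []
    if mode == "endpoints":
        for strands in model.sheets:
            for s1, s2 in zip(strands[:-1], strands[1:]):
                ends1 = [cm.index_of(s1.chain, s1.start, "CA"),
                         cm.index_of(s1.chain, s1.end, "CA")]
                ends2 = [cm.index_of(s2.chain, s2.start, "CA"),
                         cm.index_of(s2.chain, s2.end, "CA")]
                pen1 = [cm.index_of(s1.chain, s1.start + 1, "CA"),
                        cm.index_of(s1.chain, s1.end - 1, "CA")]
                pen2 = [cm.index_of(s2.chain, s2.start + 1, "CA"),
                        cm.index_of(s2.chain, s2.end - 1, "CA")]
                # spatially pair each end of s1 with the nearer end of s2
                d00 = np.linalg.norm(cm.positions[ends1[0]] - cm.positions[ends2[0]])
                d01 = np.linalg.norm(cm.positions[ends1[0]] - cm.positions[ends2[1]])
                order = (0, 1) if d00 <= d01 else (1, 0)
                for e1, e2 in ((0, order[0]), (1, order[1])):
                    pairs.append((ends1[e1], ends2[e2]))
                    pairs.append((pen1[e1], pen2[e2]))
    elif mode == "rigidify":
        for rng in _sse_ranges(model):
            idx = [i for i in range(cm.n_atoms)
                   if cm.chains[i] == rng.chain
                   and rng.start <= cm.resids[i] <= rng.end]
            for k, i in enumerate(idx):
                for j in idx[max(0, k - 3):k]:
                    pairs.append((j, i))
    else:
        raise ValueError(f"unknown SSE constraint mode: {mode!r}")
    if not pairs:
        return ConstraintSet.empty()
    return ConstraintSet.from_pairs(np.array(pairs), cm.positions)


def resolve_constraint_list(entries, cm: CoarseModel) -> ConstraintSet:
    """Turn (chain, resid, name, chain, resid, name[, dist]) tuples into a set."""
    pairs, targets = [], []
    for e in entries:
        i = cm.index_of(e[0], e[1], e[2])
        j = cm.index_of(e[3], e[4], e[5])
        pairs.append((i, j))
        if len(e) > 6 and e[6] is not None:
            targets.append(float(e[6]))
        else:
            targets.append(float(np.linalg.norm(cm.positions[i] - cm.positions[j])))
    if not pairs:
        return ConstraintSet.empty()
    return ConstraintSet(np.asarray(pairs, dtype=int), np.asarray(targets))
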