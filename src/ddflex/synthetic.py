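"""Synthetic structures and simulated maps for offline testing.

Generates idealized poly-alanine geometry (alpha-helices with 1.5 A rise and
100 degrees twist per residue, extended beta-strands with ~3.3 A CA spacing),
multi-domain hinge-motion fixtures whose ground-truth deformation is known in
closed form, and simulated density maps obtained by Gaussian projection at
sigma = R / (2 sqrt(3)) followed by subtract-and-clip thresholding.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from . import density, engine
from .grid_io import AtomicModel, DensityMap, SSERange

# masses used for generated poly-ALA models (heavy atoms only)
_MASS = {"N": 14.007, "C": 12.011, "O": 15.999}

_HELIX_RISE = 1.5          # A per residue along the axis
_HELIX_TWIST = 100.0       # degrees per residue
_HELIX_R_CA = 2.27         # CA helix radius, A
_HELIX_R_NC = 1.90         # radius used for interpolated N and C positions


def _rotation_about(axis: np.ndarray, theta: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    kx, ky, kz = axis
    k_cross = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    return (np.eye(3) + math.sin(theta) * k_cross
            + (1 - math.cos(theta)) * (k_cross @ k_cross))


def _frame_for(direction: np.ndarray) -> np.ndarray:
    """Rotation matrix whose third column is the given unit direction."""
    w = np.asarray(direction, dtype=float)
    w = w / np.linalg.norm(w)
    ref = np.array([0.0, 0.0, 1.0]) if abs(w[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(ref, w)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    return np.column_stack([u, v, w])


def _helix_residues(n_res: int, start_resid: int, chain: str,
                    origin: np.ndarray, direction: np.ndarray) -> list[dict]:
    """Idealized alpha-helix backbone (N, CA, C, O, CB) rows, poly-ALA."""
    frame = _frame_for(direction)
    rows = []

    def cyl(radius, res_frac):
        phi = math.radians(_HELIX_TWIST * res_frac)
        local = np.array([radius * math.cos(phi), radius * math.sin(phi),
                          _HELIX_RISE * res_frac])
        return origin + frame @ local

    for i in range(n_res):
        resid = start_resid + i
        n_pos = cyl(_HELIX_R_NC, i - 0.38)
        ca_pos = cyl(_HELIX_R_CA, i)
        c_pos = cyl(_HELIX_R_NC, i + 0.38)
        # carbonyl O: off C, radially outward from the helix axis
        radial = c_pos - (origin + frame @ np.array(
            [0, 0, _HELIX_RISE * (i + 0.38)]))
        radial /= np.linalg.norm(radial)
        o_pos = c_pos + 1.23 * radial
        # CB: outward from CA
        radial_ca = ca_pos - (origin + frame @ np.array([0, 0, _HELIX_RISE * i]))
        radial_ca /= np.linalg.norm(radial_ca)
        cb_pos = ca_pos + 1.53 * radial_ca
        for name, el, p in (("N", "N", n_pos), ("CA", "C", ca_pos),
                            ("C", "C", c_pos), ("O", "O", o_pos),
                            ("CB", "C", cb_pos)):
            rows.append(dict(chain=chain, resid=resid, resname="ALA", name=name,
                             element=el, mass=_MASS[el], x=p[0], y=p[1], z=p[2],
                             occ=1.0, bfac=0.0))
    return rows


def _strand_residues(n_res: int, start_resid: int, chain: str,
                     origin: np.ndarray, direction: np.ndarray,
                     perp: np.ndarray) -> list[dict]:
    """Extended (beta) backbone rows: CA zigzag with 3.3 A spacing."""
    w = np.asarray(direction, dtype=float)
    w = w / np.linalg.norm(w)
    p = np.asarray(perp, dtype=float)
    p = p - (p @ w) * w
    p /= np.linalg.norm(p)
    q = np.cross(w, p)
    rows = []
    for i in range(n_res):
        resid = start_resid + i
        zig = 0.5 * (1 if i % 2 == 0 else -1)
        ca_pos = origin + 3.3 * i * w + zig * q
        n_pos = ca_pos - 1.2 * w - 0.4 * q * (1 if i % 2 == 0 else -1)
        c_pos = ca_pos + 1.2 * w - 0.4 * q * (1 if i % 2 == 0 else -1)
        o_pos = c_pos + 1.23 * p
        cb_pos = ca_pos + 1.53 * (q if i % 2 == 0 else -q)
        for name, el, pos in (("N", "N", n_pos), ("CA", "C", ca_pos),
                              ("C", "C", c_pos), ("O", "O", o_pos),
                              ("CB", "C", cb_pos)):
            rows.append(dict(chain=chain, resid=resid, resname="ALA", name=name,
                             element=el, mass=_MASS[el], x=pos[0], y=pos[1],
                             z=pos[2], occ=1.0, bfac=0.0))
    return rows


@dataclasses.dataclass
class HingeFixture:
    """Two rigid helical domains joined by a linker; target = hinge rotation."""

    start: AtomicModel
    target: AtomicModel
    theta_deg: float
    axis_point: np.ndarray
    axis_direction: np.ndarray
    rotated_resids: list
    backbone_rmsd: float
    seed: int


def make_hinge_fixture(n_res_per_domain: int = 40, theta_deg: float = 30.0,
                       seed: int = 0) -> HingeFixture:
    """Two-domain hinge-motion fixture with closed-form ground truth.

    Domain 1 is a helix along +x ending at the hinge; a 3-residue extended
    linker continues along +x; domain 2 is a helix whose axis is tilted 30
    degrees out of the hinge axis, so a hinge rotation displaces its far end
    substantially.  The target conformation rotates domain 2 by ``theta_deg``
    about the linker (x) axis.  The seed adds a small (0.01 A) deterministic
    coordinate jitter shared by start and target, so internal within-domain
    RMSD stays zero.
    """
    n = n_res_per_domain
    rows = []
    rows += _helix_residues(n, 1, "A", np.array([0.0, 0.0, 0.0]),
                            np.array([1.0, 0.0, 0.0]))
    hinge_x = _HELIX_RISE * (n - 1) + 4.0
    rows += _strand_residues(3, n + 1, "A", np.array([hinge_x, 0.0, 0.0]),
                             np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0]))
    dom2_origin = np.array([hinge_x + 3 * 3.3 + 2.0, 0.0, 0.0])
    tilt = math.radians(30.0)
    dom2_dir = np.array([math.cos(tilt), 0.0, math.sin(tilt)])
    rows += _helix_residues(n, n + 4, "A", dom2_origin, dom2_dir)
    atoms = pd.DataFrame(rows)
    rng = np.random.default_rng(seed)
    atoms[["x", "y", "z"]] += rng.normal(0.0, 0.01, size=(len(atoms), 3))
    helices = [SSERange("A", 1, n), SSERange("A", n + 4, 2 * n + 3)]
    start = AtomicModel(atoms, helices=helices)

    axis_point = np.array([hinge_x + 1.5 * 3.3, 0.0, 0.0])
    axis_dir = np.array([1.0, 0.0, 0.0])
    rotated = list(range(n + 4, 2 * n + 4))
    target = start.copy()
    theta = math.radians(theta_deg)
    rot = _rotation_about(axis_dir, theta)
    mask = target.atoms["resid"].isin(rotated).to_numpy()
    xyz = target.coords
    xyz[mask] = (xyz[mask] - axis_point) @ rot.T + axis_point
    target.coords = xyz

    bb = start.atoms["name"].isin(engine.BACKBONE_NAMES).to_numpy()
    rmsd_val = engine.rmsd(start.coords[bb], target.coords[bb])
    return HingeFixture(start, target, theta_deg, axis_point, axis_dir,
                        rotated, rmsd_val, seed)


def make_sheet_fixture(n_strands: int = 2, len_strand: int = 4):
    """Idealized antiparallel beta-sheet with endpoint constraint list.

    Returns ``(model, constraint_entries)`` where the entries are
    ``(chain, resid, atom, chain, resid, atom)`` tuples tying the terminal and
    penultimate CA pairs of each adjacent strand pair at both ends (4 per
    adjacent pair), matching the strand register.
    """
    if len_strand < 3:
        raise ValueError("strands need at least 3 residues")
    rows = []
    strands = []
    resid = 1
    for j in range(n_strands):
        antiparallel = j % 2 == 1
        direction = np.array([-1.0 if antiparallel else 1.0, 0.0, 0.0])
        x0 = 3.3 * (len_strand - 1) if antiparallel else 0.0
        origin = np.array([x0, 4.8 * j, 0.0])
        rows += _strand_residues(len_strand, resid, "A", origin, direction,
                                 np.array([0.0, 1.0, 0.0]))
        strands.append(SSERange("A", resid, resid + len_strand - 1))
        resid += len_strand
    model = AtomicModel(pd.DataFrame(rows), sheets=[strands])
    coords = {}
    for row in model.atoms.itertuples(index=False):
        coords[(row.chain, row.resid, row.name)] = np.array([row.x, row.y, row.z])

    entries = []
    for s1, s2 in zip(strands[:-1], strands[1:]):
        ends1 = [s1.start, s1.end]
        ends2 = [s2.start, s2.end]
        pen1 = [s1.start + 1, s1.end - 1]
        pen2 = [s2.start + 1, s2.end - 1]
        d00 = np.linalg.norm(coords[("A", ends1[0], "CA")]
                             - coords[("A", ends2[0], "CA")])
        d01 = np.linalg.norm(coords[("A", ends1[0], "CA")]
                             - coords[("A", ends2[1], "CA")])
        order = (0, 1) if d00 <= d01 else (1, 0)
        for e1, e2 in ((0, order[0]), (1, order[1])):
            entries.append(("A", ends1[e1], "CA", "A", ends2[e2], "CA"))
            entries.append(("A", pen1[e1], "CA", "A", pen2[e2], "CA"))
    return model, entries


def simulate_em_map(model: AtomicModel, resolution: float,
                    grid_spacing: float = 2.0,
                    threshold_percentile: float = 60.0,
                    noise_sd: float = 0.0, seed: int = 0,
                    pad: float | None = None) -> DensityMap:
    """Simulated density map from a model at a nominal resolution R.

    The coarse-grained model is projected with a Gaussian kernel of width
    ``sigma = R / (2 sqrt(3))``; optional Gaussian voxel noise is added; the
    map is then thresholded (subtract-and-clip) at the given percentile of the
    strictly positive voxel values.  The percentile uses the 'lower' order
    statistic so the threshold is an attained map value.
    """
    sigma = resolution / (2.0 * math.sqrt(3.0))
    cm = engine.coarse_grain(model)
    if pad is None:
        pad = 4.0 * sigma + 2.0 * grid_spacing
    lo = cm.positions.min(axis=0) - pad
    hi = cm.positions.max(axis=0) + pad
    dims = np.ceil((hi - lo) / grid_spacing).astype(int) + 1
    template = DensityMap(np.zeros((dims[2], dims[1], dims[0])), lo,
                          np.full(3, float(grid_spacing)))
    gmap = density.project_model(cm.positions, cm.weights, template, sigma)
    values = gmap.values
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    positive = values[values > 0]
    t_star = float(np.quantile(positive, threshold_percentile / 100.0,
                               method="lower"))
    return gmap.like(np.clip(values - t_star, 0.0, None))
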