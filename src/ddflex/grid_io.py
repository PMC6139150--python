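"""Reading and writing of density maps, atomic models, trajectories and run logs.

Maps are MRC/CCP4-2014 files handled through :mod:`gemmi`; internally the
density values live in a fixed ``(z, y, x)`` array layout with ``origin`` and
``voxel_size`` given in Angstrom on the ``(x, y, z)`` axes, so that the voxel
``values[iz, iy, ix]`` is centred at ``origin + (ix, iy, iz) * voxel_size``.
Atomic models are PDB files (ATOM records plus HELIX/SHEET annotations).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd


class MapFormatError(ValueError):
    """Raised for density-map files this package cannot interpret."""


class ModelFormatError(ValueError):
    """Raised for atomic-model files without usable ATOM records."""


@dataclasses.dataclass
class DensityMap:
    """A 3D scalar density grid.

    Attributes
    ----------
    values : ndarray, shape (nz, ny, nx)
        Density values, arbitrary units.
    origin : ndarray, shape (3,)
        Position (x, y, z) in Angstrom of the centre of voxel [0, 0, 0].
    voxel_size : ndarray, shape (3,)
        Voxel edge lengths (x, y, z) in Angstrom.
    """

    values: np.ndarray
    origin: np.ndarray
    voxel_size: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float).reshape(3)
        if self.values.ndim != 3:
            raise MapFormatError("density grid must be 3-dimensional")
        if not np.all(self.voxel_size > 0):
            raise MapFormatError("voxel sizes must be positive")
        if not np.all(np.isfinite(self.values)):
            raise MapFormatError("density grid contains non-finite values")

    @property
    def n_voxels(self) -> int:
        return int(self.values.size)

    @property
    def shape_xyz(self) -> tuple[int, int, int]:
        nz, ny, nx = self.values.shape
        return nx, ny, nz

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    def like(self, values: np.ndarray) -> "DensityMap":
        """New map with the same geometry but different values."""
        if values.shape != self.values.shape:
            raise ValueError("shape mismatch with template grid")
        return DensityMap(values, self.origin.copy(), self.voxel_size.copy())


# one secondary-structure interval: residues start..end (inclusive) on a chain
@dataclasses.dataclass(frozen=True)
class SSERange:
    chain: str
    start: int
    end: int


@dataclasses.dataclass
class AtomicModel:
    """Per-atom records plus secondary-structure intervals.

    ``atoms`` is a DataFrame with columns
    ``chain, resid, resname, name, element, mass, x, y, z, occ, bfac``,
    ordered by chain then residue.  ``helices`` is a list of :class:`SSERange`;
    ``sheets`` is a list of sheets, each a list of strand :class:`SSERange` in
    the order given by the SHEET records.
    """

    atoms: pd.DataFrame
    helices: list = dataclasses.field(default_factory=list)
    sheets: list = dataclasses.field(default_factory=list)

    @property
    def coords(self) -> np.ndarray:
        return self.atoms[["x", "y", "z"]].to_numpy(dtype=float)

    @coords.setter
    def coords(self, xyz: np.ndarray) -> None:
        self.atoms[["x", "y", "z"]] = np.asarray(xyz, dtype=float)

    def copy(self) -> "AtomicModel":
        return AtomicModel(self.atoms.copy(), list(self.helices),
                           [list(s) for s in self.sheets])

    def residues(self):
        """Iterate (chain, resid, resname, sub-DataFrame) in file order."""
        for (chain, resid), grp in self.atoms.groupby(["chain", "resid"], sort=False):
            yield chain, int(resid), grp["resname"].iloc[0], grp


_SUPPORTED_MODES = (0, 1, 2)


def read_map(path) -> DensityMap:
    """Read an MRC/CCP4 map (modes 0/1/2, orthogonal cell only).

    Axis order is normalised via the header MAPC/MAPR/MAPS fields; the origin
    is taken from the ORIGIN header if any component is nonzero, otherwise
    from NXSTART/NYSTART/NZSTART times the voxel size.
    """
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise MapFormatError(f"cannot read map {path}: {exc}") from exc
    mode = ccp4.header_i32(4)
    if mode not in _SUPPORTED_MODES:
        raise MapFormatError(f"unsupported MRC mode {mode} (need 0, 1 or 2)")
    cell = ccp4.grid.unit_cell
    if not (abs(cell.alpha - 90) < 1e-3 and abs(cell.beta - 90) < 1e-3
            and abs(cell.gamma - 90) < 1e-3):
        raise MapFormatError("non-orthogonal cell; only orthogonal maps supported")
    # reorder axes to X-fastest without resampling
    ccp4.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    arr = np.array(ccp4.grid, copy=True)  # indexed [ix, iy, iz]
    nx, ny, nz = arr.shape
    voxel_size = np.array([cell.a / nx, cell.b / ny, cell.c / nz])
    origin = np.array([ccp4.header_float(i) for i in (50, 51, 52)])
    if np.all(origin == 0.0):
        nstart = np.array([ccp4.header_i32(i) for i in (5, 6, 7)], dtype=float)
        origin = nstart * voxel_size
    values = np.ascontiguousarray(arr.transpose(2, 1, 0))  # -> (z, y, x)
    return DensityMap(values, origin, voxel_size)


def write_map(dmap: DensityMap, path) -> None:
    """Write a map as CCP4 mode 2 (float32), storing the origin in ORIGIN."""
    nx, ny, nz = dmap.shape_xyz
    grid = gemmi.FloatGrid(nx, ny, nz)
    a, b, c = dmap.voxel_size * np.array([nx, ny, nz])
    grid.set_unit_cell(gemmi.UnitCell(a, b, c, 90.0, 90.0, 90.0))
    grid.array[:] = dmap.values.transpose(2, 1, 0).astype(np.float32)
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    for word, val in zip((50, 51, 52), dmap.origin):
        ccp4.set_header_float(word, float(val))
    ccp4.write_ccp4_map(str(path))


_STD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def read_model(path) -> AtomicModel:
    """Read a PDB file into an :class:`AtomicModel`.

    Only ATOM records are kept (HETATM ignored).  Alternate locations are
    resolved by keeping the highest-occupancy conformer (ties: first seen).
    HELIX and SHEET records are captured as residue intervals.
    """
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    rows = []
    for chain in st[0]:
        for res in chain:
            if res.het_flag == "H":
                continue
            # altloc policy: per atom name keep highest occupancy, ties -> first
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for atom in best.values():
                rows.append((chain.name, res.seqid.num, res.name, atom.name,
                             atom.element.name, atom.element.weight,
                             atom.pos.x, atom.pos.y, atom.pos.z,
                             atom.occ, atom.b_iso))
    if not rows:
        raise ModelFormatError(f"no ATOM records in {path}")
    atoms = pd.DataFrame(rows, columns=["chain", "resid", "resname", "name",
                                        "element", "mass", "x", "y", "z",
                                        "occ", "bfac"])
    helices = [SSERange(h.start.chain_name, h.start.res_id.seqid.num,
                        h.end.res_id.seqid.num) for h in st.helices]
    sheets = []
    for sheet in st.sheets:
        sheets.append([SSERange(s.start.chain_name, s.start.res_id.seqid.num,
                                s.end.res_id.seqid.num) for s in sheet.strands])
    return AtomicModel(atoms, helices, sheets)


def _format_atom_line(serial, name, resname, chain, resid, x, y, z, occ, bfac,
                      element) -> str:
    if len(name) < 4:
        name_field = f" {name:<3s}"
    else:
        name_field = name[:4]
    return (f"ATOM  {serial % 100000:5d} {name_field} {resname:<3s} "
            f"{chain[:1]:1s}{resid:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{bfac:6.2f}          "
            f"{element[:2]:>2s}")


def _sse_records(model: AtomicModel) -> list[str]:
    lines = []
    resname_of = {}
    for chain, resid, resname, _ in model.residues():
        resname_of[(chain, resid)] = resname
    for i, h in enumerate(model.helices, start=1):
        rn1 = resname_of.get((h.chain, h.start), "ALA")
        rn2 = resname_of.get((h.chain, h.end), "ALA")
        lines.append(f"HELIX  {i:3d} {i:3d} {rn1:>3s} {h.chain:1s} {h.start:4d} "
                     f" {rn2:>3s} {h.chain:1s} {h.end:4d}  1"
                     f"{'':30s} {h.end - h.start + 1:5d}")
    for si, strands in enumerate(model.sheets, start=1):
        sheet_id = chr(ord("A") + (si - 1) % 26)
        for k, s in enumerate(strands, start=1):
            rn1 = resname_of.get((s.chain, s.start), "ALA")
            rn2 = resname_of.get((s.chain, s.end), "ALA")
            sense = 0 if k == 1 else -1
            lines.append(f"SHEET  {k:3d} {sheet_id:>3s}{len(strands):2d} "
                         f"{rn1:>3s} {s.chain:1s}{s.start:4d}  "
                         f"{rn2:>3s} {s.chain:1s}{s.end:4d} {sense:2d}")
    return lines


def write_model(model: AtomicModel, path) -> None:
    """Write a single-conformation PDB with HELIX/SHEET records."""
    lines = _sse_records(model)
    serial = 0
    for row in model.atoms.itertuples(index=False):
        serial += 1
        lines.append(_format_atom_line(serial, row.name, row.resname, row.chain,
                                       row.resid, row.x, row.y, row.z,
                                       row.occ, row.bfac, row.element))
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_trajectory(models: Sequence[AtomicModel], path) -> None:
    """Write a multi-MODEL PDB trajectory (one MODEL block per conformation)."""
    models = list(models)
    if not models:
        raise ValueError("empty trajectory: need at least one model")
    lines = _sse_records(models[0])
    for imodel, model in enumerate(models, start=1):
        lines.append(f"MODEL     {imodel:4d}")
        serial = 0
        for row in model.atoms.itertuples(index=False):
            serial += 1
            lines.append(_format_atom_line(serial, row.name, row.resname,
                                           row.chain, row.resid, row.x, row.y,
                                           row.z, row.occ, row.bfac,
                                           row.element))
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_trajectory(path) -> list[AtomicModel]:
    """Read a multi-MODEL PDB back into a list of models."""
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    out = []
    for gm in st:
        rows = []
        for chain in gm:
            for res in chain:
                if res.het_flag == "H":
                    continue
                for atom in res:
                    rows.append((chain.name, res.seqid.num, res.name, atom.name,
                                 atom.element.name, atom.element.weight,
                                 atom.pos.x, atom.pos.y, atom.pos.z,
                                 atom.occ, atom.b_iso))
        if rows:
            out.append(AtomicModel(pd.DataFrame(rows, columns=[
                "chain", "resid", "resname", "name", "element", "mass",
                "x", "y", "z", "occ", "bfac"])))
    if not out:
        raise ModelFormatError(f"no models in {path}")
    return out


def write_constraints_tsv(constraints: Iterable[tuple], path) -> None:
    """Write a distance-constraint list.

    Each entry is ``(chain1, resid1, name1, chain2, resid2, name2[, dist])``;
    a missing distance means "use the current distance".
    """
    lines = ["chain1\tresid1\tatom1\tchain2\tresid2\tatom2\tdistance"]
    for c in constraints:
        dist = f"{c[6]:.4f}" if len(c) > 6 and c[6] is not None else ""
        lines.append(f"{c[0]}\t{c[1]}\t{c[2]}\t{c[3]}\t{c[4]}\t{c[5]}\t{dist}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_constraints_tsv(path) -> list[tuple]:
    df = pd.read_csv(path, sep="\t", dtype={"chain1": str, "chain2": str})
    out = []
    for row in df.itertuples(index=False):
        dist = None if pd.isna(row.distance) else float(row.distance)
        out.append((row.chain1, int(row.resid1), row.atom1,
                    row.chain2, int(row.resid2), row.atom2, dist))
    return out


def write_stopping_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2) + "\n")
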