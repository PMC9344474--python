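"""Structure and density file I/O.

Reads mmCIF/PDB coordinate files through :mod:`gemmi`, exposes atoms,
crystallographic waters and space-group symmetry, expands symmetry
mates around the asymmetric unit, and writes CCP4/MRC2014 density maps
and hydration-site pseudo-atom files.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

#: Residue names recognized as water.  DOD covers deuterated (heavy)
#: water reported by joint X-ray/neutron refinements.
WATER_RESIDUE_NAMES = frozenset({"HOH", "WAT", "DOD"})

#: Sugar atom names whose joint presence marks a nucleotide residue.
_SUGAR_MARKERS = ("C1'", "C4'")


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


class NoSymmetryError(ValueError):
    """Raised when symmetry expansion is requested without cell/space-group data."""


@dataclass(frozen=True)
class AtomRecord:
    """A single atom site with crystallographic bookkeeping.

    ``sym_op``/``sym_shift`` are set only on symmetry mates: the index of
    the generating space-group operation and the lattice translation
    applied on top of it.
    """

    atom_name: str
    element: str
    residue_name: str
    chain_id: str
    residue_number: int
    insertion_code: str
    position: np.ndarray
    occupancy: float
    b_factor: float
    altloc: str = ""
    is_water: bool = False
    is_hydrogen: bool = False
    structure_id: str = ""
    sym_op: int | None = None
    sym_shift: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.atom_name}")

    def moved_to(self, position: np.ndarray, sym_op: int, sym_shift: tuple[int, int, int]) -> "AtomRecord":
        return dataclasses.replace(self, position=np.asarray(position, float), sym_op=sym_op, sym_shift=sym_shift)


@dataclass
class Residue:
    """One residue: name, sequence id and its (altloc-resolved) atoms."""

    name: str
    chain_id: str
    number: int
    insertion_code: str
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def is_water(self) -> bool:
        return self.name in WATER_RESIDUE_NAMES

    @property
    def is_nucleotide(self) -> bool:
        names = {a.atom_name for a in self.atoms}
        return all(m in names for m in _SUGAR_MARKERS)

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.atom_name == name:
                return a
        return None

    def heavy_coords(self) -> np.ndarray:
        atoms = self.heavy_atoms()
        if not atoms:
            return np.empty((0, 3))
        return np.stack([a.position for a in atoms])


@dataclass
class StructureModel:
    """One model of a macromolecular structure.

    ``chains`` maps chain id to its ordered residue list (waters
    excluded); ``waters`` collects water O atoms from all chains.
    ``spacegroup_ops`` holds (3x3 rotation, fractional translation)
    pairs including the identity, or ``None`` when the file carries no
    crystal symmetry.
    """

    structure_id: str
    resolution: float | None
    chains: dict[str, list[Residue]]
    waters: list[AtomRecord]
    cell: tuple[float, float, float, float, float, float] | None
    spacegroup_ops: list[tuple[np.ndarray, np.ndarray]] | None
    model_number: int = 1

    def dna_residues(self) -> list[Residue]:
        return [r for residues in self.chains.values() for r in residues if r.is_nucleotide]

    def dna_heavy_coords(self) -> np.ndarray:
        coords = [r.heavy_coords() for r in self.dna_residues()]
        coords = [c for c in coords if len(c)]
        if not coords:
            return np.empty((0, 3))
        return np.vstack(coords)


@dataclass
class SymmetryExpansion:
    """Symmetry mates within a radius of the asymmetric-unit DNA."""

    source: StructureModel
    radius: float
    mates: list[AtomRecord]


def _resolve_altlocs(atoms: Sequence[gemmi.Atom]) -> list[gemmi.Atom]:
    """Keep one atom per name: the highest-occupancy altloc, ties by altloc letter."""
    by_name: dict[str, gemmi.Atom] = {}
    for a in atoms:
        prev = by_name.get(a.name)
        if prev is None:
            by_name[a.name] = a
        elif (a.occ, -ord(a.altloc or "~")) > (prev.occ, -ord(prev.altloc or "~")):
            by_name[a.name] = a
    return list(by_name.values())


def read_structure(path: str | os.PathLike, model_number: int = 1) -> StructureModel:
    """Read an mmCIF or PDB file into a :class:`StructureModel`.

    The format is auto-detected.  Only the requested model's coordinates
    are exposed (NMR ensembles default to model 1).  For each atom the
    highest-occupancy altloc is kept.  Hydrogens are retained but
    flagged; all downstream distance computations use heavy atoms only.
    """
    path = os.fspath(path)
    try:
        st = gemmi.read_structure(path)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    return _from_gemmi(st, model_number=model_number)


def read_structure_string(text: str, structure_id: str = "", model_number: int = 1) -> StructureModel:
    """Parse PDB-format text (used by tests and the synthetic corpus)."""
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse PDB text: {exc}") from exc
    if structure_id:
        st.name = structure_id
    return _from_gemmi(st, model_number=model_number)


def _from_gemmi(st: gemmi.Structure, model_number: int = 1) -> StructureModel:
    structure_id = (st.name or "").strip().lower()
    model = None
    for m in st:
        if m.num == model_number:
            model = m
            break
    if model is None:
        if model_number == 1 and len(st) > 0:
            model = st[0]
        else:
            raise StructureParseError(f"model {model_number} not present in {structure_id!r}")

    resolution = st.resolution if st.resolution and st.resolution > 0 else None

    cell = None
    if st.cell and st.cell.is_crystal():
        c = st.cell
        cell = (c.a, c.b, c.c, c.alpha, c.beta, c.gamma)

    ops = None
    sg = gemmi.find_spacegroup_by_name(st.spacegroup_hm) if st.spacegroup_hm else None
    if sg is not None and cell is not None:
        ops = []
        for op in sg.operations():
            rot = np.array(op.rot, dtype=float) / op.DEN
            tran = np.array(op.tran, dtype=float) / op.DEN
            ops.append((rot, tran))

    chains: dict[str, list[Residue]] = {}
    waters: list[AtomRecord] = []
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            resolved = _resolve_altlocs(list(res))
            is_water_res = res.name in WATER_RESIDUE_NAMES
            records = []
            for a in resolved:
                rec = AtomRecord(
                    atom_name=a.name,
                    element=a.element.name,
                    residue_name=res.name,
                    chain_id=chain.name,
                    residue_number=res.seqid.num,
                    insertion_code=(res.seqid.icode or "").strip(),
                    position=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    occupancy=float(a.occ),
                    b_factor=float(a.b_iso),
                    altloc=a.altloc or "",
                    is_water=is_water_res and a.element.name in ("O", "D"),
                    is_hydrogen=bool(a.element.is_hydrogen),
                    structure_id=structure_id,
                )
                records.append(rec)
            if is_water_res:
                for rec in records:
                    if rec.is_water:
                        if rec.occupancy == 0.0:
                            logger.info("water %s %s/%d has zero occupancy; retained",
                                        structure_id, chain.name, res.seqid.num)
                        waters.append(rec)
            else:
                residue = Residue(
                    name=res.name,
                    chain_id=chain.name,
                    number=res.seqid.num,
                    insertion_code=(res.seqid.icode or "").strip(),
                    atoms=records,
                )
                residues.append(residue)
        if residues:
            residues.sort(key=lambda r: (r.number, r.insertion_code))
            chains[chain.name] = residues

    return StructureModel(
        structure_id=structure_id,
        resolution=resolution,
        chains=chains,
        waters=waters,
        cell=cell,
        spacegroup_ops=ops,
        model_number=model.num,
    )


def expand_symmetry(model: StructureModel, radius: float, what: str = "waters-only") -> SymmetryExpansion:
    """Generate symmetry mates within ``radius`` of the ASU DNA heavy atoms.

    Applies every space-group operation combined with all lattice
    translations whose images can fall within ``radius`` of the DNA
    bounding box; images produced by the identity operation with zero
    lattice shift are excluded (they duplicate the asymmetric unit).

    ``what`` selects the atoms to replicate: ``"waters-only"`` or
    ``"all-atoms"`` (heavy atoms of all residues plus waters).
    """
    if what not in ("waters-only", "all-atoms"):
        raise ValueError(f"unknown expansion mode {what!r}")
    if model.cell is None or model.spacegroup_ops is None:
        raise NoSymmetryError(
            f"structure {model.structure_id!r} lacks cell or space-group metadata"
        )
    if radius <= 0:
        return SymmetryExpansion(source=model, radius=radius, mates=[])

    dna = model.dna_heavy_coords()
    if len(dna) == 0:
        return SymmetryExpansion(source=model, radius=radius, mates=[])
    tree = cKDTree(dna)

    cell = gemmi.UnitCell(*model.cell)
    orth = np.array(cell.orth.mat.tolist())
    frac = np.array(cell.frac.mat.tolist())

    if what == "waters-only":
        source_atoms = list(model.waters)
    else:
        source_atoms = [a for residues in model.chains.values() for r in residues
                        for a in r.heavy_atoms()]
        source_atoms += list(model.waters)
    if not source_atoms:
        return SymmetryExpansion(source=model, radius=radius, mates=[])
    src_xyz = np.stack([a.position for a in source_atoms])
    src_frac = src_xyz @ frac.T

    # Fractional bounding box of the DNA region inflated by radius: take
    # the 8 corners of the inflated Cartesian box (covers oblique cells).
    lo = dna.min(axis=0) - radius
    hi = dna.max(axis=0) + radius
    corners = np.array([[x, y, z] for x in (lo[0], hi[0])
                        for y in (lo[1], hi[1]) for z in (lo[2], hi[2])])
    fcorners = corners @ frac.T
    flo, fhi = fcorners.min(axis=0), fcorners.max(axis=0)

    mates: list[AtomRecord] = []
    for op_idx, (rot, tran) in enumerate(model.spacegroup_ops):
        img = src_frac @ rot.T + tran
        identity_op = np.allclose(rot, np.eye(3)) and np.allclose(tran % 1.0, 0.0)
        # lattice shift range so that img + n overlaps [flo, fhi]
        n_lo = np.floor(flo - img.max(axis=0)).astype(int) - 1
        n_hi = np.ceil(fhi - img.min(axis=0)).astype(int) + 1
        for nx in range(n_lo[0], n_hi[0] + 1):
            for ny in range(n_lo[1], n_hi[1] + 1):
                for nz in range(n_lo[2], n_hi[2] + 1):
                    shift = np.array([nx, ny, nz], float)
                    if identity_op and np.allclose(tran + shift, 0.0):
                        continue
                    cart = (img + shift) @ orth.T
                    d, _ = tree.query(cart, distance_upper_bound=radius)
                    sel = np.where(d <= radius)[0]
                    for i in sel:
                        mates.append(source_atoms[i].moved_to(cart[i], op_idx, (nx, ny, nz)))
    return SymmetryExpansion(source=model, radius=radius, mates=mates)


def extract_waters(model: StructureModel, expansion: SymmetryExpansion | None = None) -> list[AtomRecord]:
    """ASU water O atoms plus symmetry-mate waters when an expansion is supplied."""
    waters = list(model.waters)
    if expansion is not None:
        waters += [a for a in expansion.mates if a.is_water]
    return waters


def write_density_map(grid: "GridDensity", path: str | os.PathLike) -> None:
    """Write a density grid as a CCP4/MRC2014 mode-2 map.

    Axes are orthogonal, voxel size equals the grid spacing and the
    Cartesian origin is recorded in the MRC ORIGIN header words, so the
    map overlays the source coordinates in standard viewers.
    """
    values = np.asarray(grid.values, dtype=np.float32)
    if values.ndim != 3 or min(values.shape) < 1:
        raise ValueError("grid must be 3-dimensional with dims >= 1")
    nx, ny, nz = values.shape
    g = gemmi.FloatGrid(nx, ny, nz)
    g.set_unit_cell(gemmi.UnitCell(nx * grid.spacing, ny * grid.spacing,
                                   nz * grid.spacing, 90.0, 90.0, 90.0))
    np.asarray(g.array)[:] = values
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = g
    ccp4.update_ccp4_header()
    ox, oy, oz = np.asarray(grid.origin, dtype=float)
    ccp4.set_header_float(50, float(ox))
    ccp4.set_header_float(51, float(oy))
    ccp4.set_header_float(52, float(oz))
    ccp4.write_ccp4_map(os.fspath(path))


def read_density_map(path: str | os.PathLike):
    """Round-trip companion to :func:`write_density_map`.

    Returns ``(values, origin, spacing)``.
    """
    m = gemmi.read_ccp4_map(os.fspath(path))
    values = np.array(m.grid.array, dtype=np.float32)
    origin = np.array([m.header_float(50), m.header_float(51), m.header_float(52)])
    spacing = m.grid.unit_cell.a / m.grid.nu
    return values, origin, spacing


#: Residue names used for hydration-site pseudo-waters by category.
SITE_RESIDUE_NAMES = {"base": "HSB", "backbone": "HSK"}


def write_hydration_sites(sites: Iterable, path: str | os.PathLike) -> None:
    """Write hydration sites as water-like O pseudo-atoms in PDB format.

    The occupancy column carries the site occupancy clamped to [0, 1];
    the B-factor column carries the peak density scaled by 10 (capped at
    999.99) so relative peak heights survive the fixed-width format.
    Base-category sites use residue name HSB, backbone HSK.
    """
    lines = []
    for i, s in enumerate(sites, start=1):
        resname = SITE_RESIDUE_NAMES.get(s.category, "HSX")
        x, y, z = np.asarray(s.position, dtype=float)
        occ = min(1.0, max(0.0, float(s.occupancy)))
        b = min(999.99, 10.0 * float(s.peak_value))
        lines.append(
            f"HETATM{i:5d}  O   {resname:<3s} W{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}           O"
        )
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
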