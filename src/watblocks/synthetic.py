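"""Self-contained synthetic fixtures: idealized DNA, planted hydration.

Idealized single-stranded B- or A-form DNA is built from internal
coordinates (ideal bond lengths/angles, canonical backbone torsions)
by natural-extension-reference-frame chaining, with planar idealized
base geometry.  The sugar ring is generated from ring torsions and
closes only approximately; the geometry is chemically sensible and
fully deterministic, which is what the pipeline tests need — the
fixtures exercise machinery, not hydration biology.

A corpus generator scatters rigid-body copies of one dinucleotide,
plants hydration sites with stated occupancies and positional jitter,
and emits both structure models and the ground-truth table.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fragments import (BACKBONE_ATOMS, DinucleotideStep, NucleotideResidue,
                        extract_steps)
from .structure_io import AtomRecord, Residue, StructureModel

# ---------------------------------------------------------------------------
# internal-coordinate machinery

def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom D bonded to C given bond C-D, angle B-C-D and torsion A-B-C-D."""
    ab = b - a
    bc = c - b
    bc_u = bc / np.linalg.norm(bc)
    n = np.cross(ab, bc_u)
    n_u = n / np.linalg.norm(n)
    m = np.cross(n_u, bc_u)
    th = np.radians(angle)
    ph = np.radians(torsion)
    d_local = np.array([-bond * np.cos(th),
                        bond * np.sin(th) * np.cos(ph),
                        -bond * np.sin(th) * np.sin(ph)])
    return c + d_local[0] * bc_u + d_local[1] * m + d_local[2] * n_u


#: Canonical backbone torsions (degrees) of the two helical families.
#: Keys follow the conventional alpha..zeta/chi naming; delta encodes
#: the sugar pucker (C2'-endo for B, C3'-endo for A).
FORM_TORSIONS = {
    "B": {"alpha": 299.0, "beta": 179.0, "gamma": 48.0, "delta": 129.0,
          "epsilon": 185.0, "zeta": 264.0, "chi": 258.0},
    "A": {"alpha": 295.0, "beta": 173.0, "gamma": 54.0, "delta": 82.0,
          "epsilon": 205.0, "zeta": 287.0, "chi": 205.0},
}

_BONDS = {("P", "O5'"): 1.59, ("O5'", "C5'"): 1.44, ("C5'", "C4'"): 1.51,
          ("C4'", "C3'"): 1.52, ("C3'", "O3'"): 1.42, ("O3'", "P"): 1.60}
_ANGLES = {"P-O5'-C5'": 119.0, "O5'-C5'-C4'": 111.0, "C5'-C4'-C3'": 116.0,
           "C4'-C3'-O3'": 110.0, "C3'-O3'-P": 119.0, "O3'-P-O5'": 104.0}


def _regular_polygon(n: int, bond: float) -> np.ndarray:
    """Vertices of a regular n-gon with given edge length, centred at 0."""
    r = bond / (2 * np.sin(np.pi / n))
    ang = np.pi / 2 - 2 * np.pi * np.arange(n) / n
    return np.stack([r * np.cos(ang), r * np.sin(ang)], axis=1)


def _exocyclic(ring_xy: np.ndarray, vertex: int, bond: float) -> np.ndarray:
    v = ring_xy[vertex]
    out = v / np.linalg.norm(v)
    return v + bond * out


def _pyrimidine_template(base: str) -> dict[str, np.ndarray]:
    """Planar pyrimidine: hexagon N1 C2 N3 C4 C5 C6 plus exocyclic atoms."""
    ring = _regular_polygon(6, 1.37)
    names = ["N1", "C2", "N3", "C4", "C5", "C6"]
    atoms = dict(zip(names, ring))
    atoms["O2"] = _exocyclic(ring, 1, 1.23)
    if base == "C":
        atoms["N4"] = _exocyclic(ring, 3, 1.34)
    else:  # T
        atoms["O4"] = _exocyclic(ring, 3, 1.23)
        atoms["C7"] = _exocyclic(ring, 4, 1.50)
    return atoms


def _purine_template(base: str) -> dict[str, np.ndarray]:
    """Planar purine: hexagon N1..C6 fused with pentagon C4-C5-N7-C8-N9."""
    hexagon = _regular_polygon(6, 1.39)
    names = ["N1", "C2", "N3", "C4", "C5", "C6"]
    atoms = dict(zip(names, hexagon))
    c4, c5 = atoms["C4"], atoms["C5"]
    mid = (c4 + c5) / 2
    edge = c5 - c4
    # outward normal: away from the hexagon centre (origin)
    normal = np.array([-edge[1], edge[0]])
    if np.dot(normal, mid) < 0:
        normal = -normal
    normal /= np.linalg.norm(normal)
    edge_len = np.linalg.norm(edge)
    apothem = edge_len / (2 * np.tan(np.pi / 5))
    r5 = edge_len / (2 * np.sin(np.pi / 5))
    centre5 = mid + apothem * normal
    # pentagon order around: C4, C5, N7, C8, N9
    start = np.arctan2(c4[1] - centre5[1], c4[0] - centre5[0])
    sweep = np.arctan2(c5[1] - centre5[1], c5[0] - centre5[0]) - start
    sweep = (sweep + np.pi) % (2 * np.pi) - np.pi  # signed step C4->C5
    for k, name in enumerate(["N7", "C8", "N9"], start=2):
        ang = start + sweep * k
        atoms[name] = centre5 + r5 * np.array([np.cos(ang), np.sin(ang)])
    if base == "A":
        atoms["N6"] = _exocyclic(hexagon, 5, 1.34)
    else:  # G
        atoms["O6"] = _exocyclic(hexagon, 5, 1.23)
        atoms["N2"] = _exocyclic(hexagon, 1, 1.34)
    return atoms


def _base_template(base: str) -> tuple[dict[str, np.ndarray], str, str]:
    """2D base template re-framed with the glycosidic N at the origin and
    the chi-defining ring atom on +x.  Returns (coords, N name, C name)."""
    if base in "AG":
        atoms, n_name, c_name = _purine_template(base), "N9", "C4"
    else:
        atoms, n_name, c_name = _pyrimidine_template(base), "N1", "C2"
    origin = atoms[n_name]
    shifted = {k: v - origin for k, v in atoms.items()}
    x_dir = shifted[c_name] / np.linalg.norm(shifted[c_name])
    rot = np.array([[x_dir[0], x_dir[1]], [-x_dir[1], x_dir[0]]])
    return {k: rot @ v for k, v in shifted.items()}, n_name, c_name


_RESIDUE_NAME = {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}


def _sugar_ring(c4: np.ndarray, c3: np.ndarray, c5: np.ndarray,
                o5: np.ndarray, o3: np.ndarray) -> dict[str, np.ndarray]:
    """Place O4', C1', C2' as a planar regular pentagon on the C4'-C3' edge.

    The ring plane is an idealization (real deoxyribose is puckered);
    its orientation about the C4'-C3' axis is chosen so the exocyclic
    C5'-C4'-O4' and C2'-C3'-O3' angles come out near-tetrahedral and no
    ring atom clashes with the backbone O atoms.
    """
    ab = c3 - c4
    e = float(np.linalg.norm(ab))
    ab_u = ab / e
    ref = c5 - c4
    u = ref - np.dot(ref, ab_u) * ab_u
    u /= np.linalg.norm(u)
    v = np.cross(ab_u, u)
    apo = e / (2 * np.tan(np.pi / 5))
    circ = e / (2 * np.sin(np.pi / 5))

    def angle(a, b, c):
        p, q = a - b, c - b
        return np.degrees(np.arccos(np.clip(
            np.dot(p, q) / (np.linalg.norm(p) * np.linalg.norm(q)), -1, 1)))

    best = None
    for phi_deg in range(360):
        phi = np.radians(phi_deg)
        d = np.cos(phi) * u + np.sin(phi) * v
        centre = (c4 + c3) / 2 + apo * d
        m = np.cross(ab_u, d)
        x = c4 - centre
        x /= np.linalg.norm(x)
        y = np.cross(m, x)
        a3 = np.arctan2(np.dot(c3 - centre, y), np.dot(c3 - centre, x))
        step = np.sign(a3) * 2 * np.pi / 5
        ring = {}
        for k, name in enumerate(("O4'", "C1'", "C2'"), start=1):
            a = -step * k
            ring[name] = centre + circ * (np.cos(a) * x + np.sin(a) * y)
        score = (abs(angle(c5, c4, ring["O4'"]) - 109)
                 + abs(angle(ring["C2'"], c3, o3) - 109))
        if min(np.linalg.norm(ring[k] - o3) for k in ("O4'", "C1'")) < 2.0:
            continue
        if min(np.linalg.norm(ring[k] - o5) for k in ring) < 2.0:
            continue
        if best is None or score < best[0]:
            best = (score, ring)
    if best is None:  # pragma: no cover - geometry always admits a solution
        raise RuntimeError("sugar ring placement failed")
    return best[1]


def build_chain(seq: str, form: str = "B", chain_id: str = "A",
                structure_id: str = "synth") -> list[Residue]:
    """Build an idealized single DNA strand with standard atom names.

    Every consecutive dinucleotide step has identical internal geometry
    (canonical torsions of the requested helical family), so a chain of
    n nucleotides yields n-1 congruent steps.  The 5'-terminal residue
    carries no phosphate group.
    """
    seq = seq.upper()
    if not seq or any(ch not in "ACGT" for ch in seq):
        raise ValueError(f"sequence must be over ACGT, got {seq!r}")
    if form not in FORM_TORSIONS:
        raise ValueError(f"unknown form {form!r}; use 'B' or 'A'")
    t = FORM_TORSIONS[form]

    # seed the first three main-chain atoms (O5', C5', C4' of residue 1)
    coords: list[tuple[int, str, np.ndarray]] = []  # (residue index, atom, xyz)
    o5 = np.zeros(3)
    c5 = np.array([_BONDS[("O5'", "C5'")], 0.0, 0.0])
    th = np.radians(180.0 - _ANGLES["O5'-C5'-C4'"])
    c4 = c5 + _BONDS[("C5'", "C4'")] * np.array([np.cos(th), np.sin(th), 0.0])

    main: dict[tuple[int, str], np.ndarray] = {(0, "O5'"): o5, (0, "C5'"): c5, (0, "C4'"): c4}
    # chain extension recipe: each entry places `atom` of residue i+di
    recipe = [
        ("C3'", 0, ("O5'", 0), ("C5'", 0), ("C4'", 0), _BONDS[("C4'", "C3'")], _ANGLES["C5'-C4'-C3'"], "gamma"),
        ("O3'", 0, ("C5'", 0), ("C4'", 0), ("C3'", 0), _BONDS[("C3'", "O3'")], _ANGLES["C4'-C3'-O3'"], "delta"),
        ("P", 1, ("C4'", 0), ("C3'", 0), ("O3'", 0), _BONDS[("O3'", "P")], _ANGLES["C3'-O3'-P"], "epsilon"),
        ("O5'", 1, ("C3'", 0), ("O3'", 0), ("P", 1), _BONDS[("P", "O5'")], _ANGLES["O3'-P-O5'"], "zeta"),
        ("C5'", 1, ("O3'", 0), ("P", 1), ("O5'", 1), _BONDS[("O5'", "C5'")], _ANGLES["P-O5'-C5'"], "alpha"),
        ("C4'", 1, ("P", 1), ("O5'", 1), ("C5'", 1), _BONDS[("C5'", "C4'")], _ANGLES["O5'-C5'-C4'"], "beta"),
    ]
    for i in range(len(seq)):
        for atom, di, a, b, c, bond, angle, tors in recipe:
            tgt = (i + di, atom)
            if tgt in main or i + di >= len(seq):
                continue
            pa = main[(i + a[1], a[0])]
            pb = main[(i + b[1], b[0])]
            pc = main[(i + c[1], c[0])]
            main[tgt] = _nerf(pa, pb, pc, bond, angle, t[tors])

    residues: list[Residue] = []
    for i, base in enumerate(seq):
        atom_xyz: dict[str, np.ndarray] = {
            name: main[(i, name)] for name in ("P", "O5'", "C5'", "C4'", "C3'", "O3'")
            if (i, name) in main
        }
        # phosphate O atoms, staggered around the P against O3'(i-1)
        if "P" in atom_xyz:
            prev_o3 = main[(i - 1, "O3'")]
            from .fragments import dihedral as _dih
            t_o3 = _dih(atom_xyz["C5'"], atom_xyz["O5'"], atom_xyz["P"], prev_o3)
            atom_xyz["OP1"] = _nerf(atom_xyz["C5'"], atom_xyz["O5'"], atom_xyz["P"],
                                    1.48, 108.0, t_o3 + 120.0)
            atom_xyz["OP2"] = _nerf(atom_xyz["C5'"], atom_xyz["O5'"], atom_xyz["P"],
                                    1.48, 108.0, t_o3 + 240.0)
        # sugar ring (planar-pentagon idealization)
        atom_xyz.update(_sugar_ring(atom_xyz["C4'"], atom_xyz["C3'"],
                                    atom_xyz["C5'"], atom_xyz["O5'"], atom_xyz["O3'"]))
        # glycosidic N: out of the (planar) ring, trans to C4' across O4'-C1'
        n_pos = _nerf(atom_xyz["C4'"], atom_xyz["O4'"], atom_xyz["C1'"], 1.47, 108.0, 240.0)
        template, n_name, c_name = _base_template(base)
        c_chi = _nerf(atom_xyz["O4'"], atom_xyz["C1'"], n_pos,
                      float(np.linalg.norm(template[c_name])), 118.0, t["chi"])
        e1 = c_chi - n_pos
        e1 /= np.linalg.norm(e1)
        helper = atom_xyz["C1'"] - n_pos
        normal = np.cross(helper, e1)
        normal /= np.linalg.norm(normal)
        e2 = np.cross(normal, e1)
        atom_xyz[n_name] = n_pos
        neighbour = "C8" if base in "AG" else "C6"  # other ring atom bonded to N
        for flip in (1.0, -1.0):
            placed = {name: n_pos + xy[0] * e1 + flip * xy[1] * e2
                      for name, xy in template.items() if name != n_name}
            if np.linalg.norm(placed[neighbour] - atom_xyz["C1'"]) > 2.0:
                atom_xyz.update(placed)
                break
        else:
            atom_xyz.update(placed)

        resname = _RESIDUE_NAME[base]
        atoms = [AtomRecord(atom_name=name, element=name[0] if name[0].isalpha() else name[1],
                            residue_name=resname, chain_id=chain_id, residue_number=i + 1,
                            insertion_code="", position=xyz, occupancy=1.0, b_factor=10.0,
                            structure_id=structure_id)
                 for name, xyz in atom_xyz.items()]
        residues.append(Residue(name=resname, chain_id=chain_id, number=i + 1,
                                insertion_code="", atoms=atoms))
    return residues


def make_ideal_step(seq2: str, form: str = "B") -> DinucleotideStep:
    """An idealized dinucleotide step of the given 2-letter sequence."""
    if len(seq2) != 2:
        raise ValueError(f"seq2 must have length 2, got {seq2!r}")
    residues = build_chain(seq2, form=form)
    steps = extract_steps(residues, structure_id=f"ideal-{form}-{seq2}")
    assert len(steps) == 1
    return steps[0]


# ---------------------------------------------------------------------------
# planted hydration

@dataclass(frozen=True)
class PlantedSite:
    """A hydration site planted in the reference frame of a step."""

    offset: tuple[float, float, float]
    occupancy: float
    jitter: float
    category: str  # "base" or "backbone"

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must be in [0, 1]")


def default_planted_sites(step: DinucleotideStep,
                          occupancies: tuple[float, ...] = (0.9, 0.6, 0.4, 0.2),
                          jitter: float = 0.25,
                          contact: float = 2.8) -> list[PlantedSite]:
    """Plant sites 2.8 A outside chosen anchor atoms of a step.

    Two sites sit off base atoms (hydrogen-bond distance from the base
    edge) and two off backbone O atoms, mimicking base-edge hydration
    and the phosphate cone of hydration.  Anchors are chosen so the
    sites are mutually separated by at least 2 A.
    """
    centroid = step.heavy_coords().mean(axis=0)

    def outward(atom):
        d = atom.position - centroid
        return atom.position + contact * d / np.linalg.norm(d)

    base1 = max(step.first.base_atoms, key=lambda a: np.linalg.norm(a.position - centroid))
    base2 = max(step.second.base_atoms, key=lambda a: np.linalg.norm(a.position - centroid))
    op2 = step.second.atom("OP2") or step.second.atom("OP1")
    o3 = step.second.atom("O3'")
    anchors = [(base1, "base"), (base2, "base"), (op2, "backbone"), (o3, "backbone")]
    sites = []
    for (atom, category), occ in zip(anchors, occupancies):
        if atom is None:
            raise ValueError("step lacks an anchor atom for planted sites")
        sites.append(PlantedSite(offset=tuple(outward(atom)), occupancy=occ,
                                 jitter=jitter, category=category))
    positions = np.array([s.offset for s in sites])
    dmat = np.linalg.norm(positions[:, None] - positions[None, :], axis=2)
    np.fill_diagonal(dmat, np.inf)
    if dmat.min() < 2.0:
        raise ValueError(f"planted sites too close: min separation {dmat.min():.2f} A")
    return sites


def plant_waters(step: DinucleotideStep, sites: list[PlantedSite], seed: int,
                 structure_id: str = "synth", start_number: int = 101) -> list[AtomRecord]:
    """Draw waters at planted sites: each site yields one water with
    probability equal to its occupancy, jittered isotropically."""
    rng = np.random.default_rng(seed)
    waters = []
    num = start_number
    for site in sites:
        present = rng.random() < site.occupancy
        noise = rng.normal(0.0, site.jitter, 3) if site.jitter > 0 else np.zeros(3)
        if present:
            pos = np.asarray(site.offset) + noise
            waters.append(AtomRecord(
                atom_name="O", element="O", residue_name="HOH",
                chain_id=step.first.chain_id or "A", residue_number=num,
                insertion_code="", position=pos, occupancy=1.0, b_factor=20.0,
                is_water=True, structure_id=structure_id))
            num += 1
    return waters


# ---------------------------------------------------------------------------
# corpus generation

@dataclass
class SyntheticSpec:
    """Conditions of a synthetic hydrated-dinucleotide corpus."""

    n_structures: int = 100
    seq2: str = "GC"
    form: str = "B"
    planted_sites: list[PlantedSite] = field(default_factory=list)
    rotation: bool = True
    translation_range: float = 20.0
    coordinate_noise: float = 0.0
    crystal_cell: bool = False
    seed: int = 0


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation from a normalized quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


@dataclass
class SyntheticCorpus:
    """Generated structures plus their ground truth."""

    spec: SyntheticSpec
    reference_step: DinucleotideStep
    models: list[StructureModel]
    ground_truth: pd.DataFrame  # structure_id, site index, x, y, z, occupancy, category


def make_corpus(spec: SyntheticSpec) -> SyntheticCorpus:
    """Scatter rigid copies of one ideal step with planted hydration.

    Each structure is a random rigid transform of the ideal dinucleotide
    (optional isotropic atom noise applied first), with waters drawn at
    the planted sites and transformed identically.  The ground-truth
    table lists the transformed site positions and their occupancies.
    Fixed seed gives byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    ref = make_ideal_step(spec.seq2, form=spec.form)
    sites = spec.planted_sites or default_planted_sites(ref)

    models = []
    rows = []
    for k in range(spec.n_structures):
        sid = f"syn{k:04d}"
        R = _random_rotation(rng) if spec.rotation else np.eye(3)
        t = rng.uniform(-spec.translation_range, spec.translation_range, 3)
        waters = plant_waters(ref, sites, seed=int(rng.integers(2 ** 31)), structure_id=sid)

        residues = []
        for res in (ref.first, ref.second):
            atoms = []
            for a in res.atoms:
                pos = a.position
                if spec.coordinate_noise > 0:
                    pos = pos + rng.normal(0.0, spec.coordinate_noise, 3)
                atoms.append(dataclasses.replace(a, position=R @ pos + t, structure_id=sid))
            residues.append(Residue(name=res.residue_name, chain_id="A",
                                    number=res.number, insertion_code="", atoms=atoms))
        twaters = [dataclasses.replace(w, position=R @ w.position + t, structure_id=sid)
                   for w in waters]

        cell = None
        ops = None
        if spec.crystal_cell:
            span = np.ptp(np.vstack([r.heavy_coords() for r in residues]), axis=0)
            dims = span + 6.0
            cell = (float(dims[0]), float(dims[1]), float(dims[2]), 90.0, 90.0, 90.0)
            ops = [(np.eye(3), np.zeros(3))]
        models.append(StructureModel(structure_id=sid, resolution=1.0,
                                     chains={"A": residues}, waters=twaters,
                                     cell=cell, spacegroup_ops=ops))
        for j, s in enumerate(sites):
            pos = R @ np.asarray(s.offset) + t
            rows.append({"structure_id": sid, "site": j,
                         "x": pos[0], "y": pos[1], "z": pos[2],
                         "occupancy": s.occupancy, "category": s.category})
    truth = pd.DataFrame(rows)
    return SyntheticCorpus(spec=spec, reference_step=ref, models=models, ground_truth=truth)


# ---------------------------------------------------------------------------
# PDB output

def model_to_pdb(model: StructureModel) -> str:
    """Serialize a StructureModel as PDB text (coordinates + waters)."""
    lines = []
    if model.cell is not None:
        a, b, c, al, be, ga = model.cell
        lines.append(f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{al:7.2f}{be:7.2f}{ga:7.2f} P 1")
    serial = 1

    def fmt(record, a: AtomRecord):
        nonlocal serial
        name = a.atom_name if len(a.atom_name) >= 4 else f" {a.atom_name:<3s}"
        x, y, z = a.position
        line = (f"{record:<6s}{serial:5d} {name:<4s} {a.residue_name:<3s} "
                f"{a.chain_id:1s}{a.residue_number:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{a.b_factor:6.2f}"
                f"          {a.element:>2s}")
        serial += 1
        return line

    for residues in model.chains.values():
        for res in residues:
            for a in res.atoms:
                lines.append(fmt("ATOM", a))
    for w in model.waters:
        lines.append(fmt("HETATM", w))
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_corpus(corpus: SyntheticCorpus, directory: str | Path) -> None:
    """Write each model as a PDB file plus the ground-truth TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for model in corpus.models:
        (directory / f"{model.structure_id}.pdb").write_text(model_to_pdb(model))
    corpus.ground_truth.to_csv(directory / "ground_truth.tsv", sep="\t", index=False,
                               float_format="%.6f")
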