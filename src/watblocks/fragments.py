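"""Dinucleotide steps: extraction, atom partition and conformer labels.

A DNA chain is split into overlapping dinucleotide steps (residues i,
i+1 joined by the O3'-P linkage).  Each step carries a two-letter
sequence and an NtC conformer-class label; labels come either from an
externally produced assignment table or from a simplified
nearest-centroid classifier over nine backbone/glycosidic torsions.
The full NtC classification protocol is an external service and is not
reimplemented here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .structure_io import AtomRecord, Residue

logger = logging.getLogger(__name__)

#: Heavy-atom names of the sugar-phosphate backbone.  C1' and O4'
#: belong to the sugar and hence to the backbone category even though
#: O4' takes part in minor-groove water bridges; the partition follows
#: covalent identity, not hydrogen-bonding role.
BACKBONE_ATOMS = frozenset({
    "P", "OP1", "OP2", "OP3", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "C1'",
})

#: Map residue names to parent one-letter codes.  Modified nucleotides
#: map to their parent base; residues absent from this table break the
#: chain at that point.  Extendable by the caller.
RESIDUE_ONE_LETTER: dict[str, str] = {
    "DA": "A", "DC": "C", "DG": "G", "DT": "T",
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "5CM": "C", "5MC": "C",   # 5-methylcytosine
    "BRU": "T", "5BU": "T",   # 5-bromouridine
    "DI": "G",                # inosine treated as G-like
    "8OG": "G",               # 8-oxoguanine
}

#: Fixed NtC conformer-class vocabulary: 96 dinucleotide conformer
#: mnemonics plus NANT for unassignable steps.  The two leading letters
#: encode the sugar puckers of the two nucleotides (A-like/B-like/other
#: families); BB00/BB01 cover the BI form, BB07 BII, AA00 the canonical
#: A form and ZZ1S/ZZS1 Z-DNA.
NTC_CLASSES: tuple[str, ...] = tuple(
    [f"AA{i:02d}" for i in range(14)]                      # AA00..AA13
    + [f"AB{i:02d}" for i in range(1, 6)]                  # AB01..AB05
    + ["AB1S", "AB2S", "AAS1"]
    + ["BA01", "BA05", "BA08", "BA09", "BA10", "BA13", "BA16", "BA17"]
    + ["BB00", "BB01", "BB02", "BB03", "BB04", "BB05", "BB07", "BB08",
       "BB10", "BB11", "BB12", "BB13", "BB14", "BB15", "BB16", "BB17", "BB20"]
    + ["BB1S", "BB2S", "BBS1"]
    + ["ZZ01", "ZZ02", "ZZ1S", "ZZ2S", "ZZS1", "ZZS2"]
    + [f"IC{i:02d}" for i in range(1, 8)]                  # IC01..IC07
    + [f"OP{i:02d}" for i in range(1, 32)]                 # OP01..OP31
    + ["OPS1", "OP1S"]
)
assert len(NTC_CLASSES) == 96

NANT = "NANT"
NTC_VOCABULARY: tuple[str, ...] = NTC_CLASSES + (NANT,)

#: The nine torsions used by the simplified classifier, in fixed order.
TORSION_NAMES = ("delta1", "epsilon1", "zeta1", "alpha2", "beta2", "gamma2",
                 "delta2", "chi1", "chi2")

_PURINE_GLYCO = ("N9", "C4")
_PYRIMIDINE_GLYCO = ("N1", "C2")
_PURINES = frozenset("AG")


@dataclass
class NucleotideResidue:
    """A nucleotide with its heavy atoms partitioned into base and backbone."""

    residue_name: str
    one_letter: str
    atoms: list[AtomRecord]
    chain_id: str = ""
    number: int = 0
    insertion_code: str = ""

    @classmethod
    def from_residue(cls, res: Residue, mapping: dict[str, str] | None = None) -> "NucleotideResidue | None":
        mapping = mapping if mapping is not None else RESIDUE_ONE_LETTER
        one = mapping.get(res.name)
        if one is None:
            return None
        return cls(residue_name=res.name, one_letter=one, atoms=res.heavy_atoms(),
                   chain_id=res.chain_id, number=res.number,
                   insertion_code=res.insertion_code)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.atom_name == name:
                return a
        return None

    @property
    def base_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.atom_name not in BACKBONE_ATOMS]

    @property
    def backbone_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.atom_name in BACKBONE_ATOMS]


def partition_atoms(residue: NucleotideResidue) -> tuple[list[AtomRecord], list[AtomRecord]]:
    """Partition a residue's heavy atoms into (base, backbone) by atom name."""
    if not residue.atoms:
        raise ValueError("residue has no heavy atoms")
    return residue.base_atoms, residue.backbone_atoms


@dataclass
class DinucleotideStep:
    """Two covalently linked nucleotides at chain positions i, i+1."""

    first: NucleotideResidue
    second: NucleotideResidue
    ntc: str = NANT
    source: tuple[str, str, int] = ("", "", 0)  # (structure_id, chain_id, resnum of i)

    @property
    def seq2(self) -> str:
        return self.first.one_letter + self.second.one_letter

    def heavy_atoms(self) -> list[tuple[str, AtomRecord]]:
        """Heavy atoms labeled by (residue slot, atom name)."""
        out = []
        for slot, res in (("1", self.first), ("2", self.second)):
            for a in res.atoms:
                out.append((slot + ":" + a.atom_name, a))
        return out

    def heavy_coords(self) -> np.ndarray:
        return np.stack([a.position for _, a in self.heavy_atoms()])

    def labeled_coords(self) -> dict[str, np.ndarray]:
        return {lab: a.position for lab, a in self.heavy_atoms()}

    def base_atoms(self) -> list[AtomRecord]:
        return self.first.base_atoms + self.second.base_atoms

    def backbone_atoms(self) -> list[AtomRecord]:
        return self.first.backbone_atoms + self.second.backbone_atoms


#: O3'(i)-P(i+1) covalent-linkage cutoff: generous versus the ~1.6 A
#: bond, but short enough to exclude lattice neighbours.
LINKAGE_CUTOFF = 2.5


def extract_steps(chain: list, structure_id: str = "",
                  mapping: dict[str, str] | None = None,
                  linkage_cutoff: float = LINKAGE_CUTOFF) -> list[DinucleotideStep]:
    """Split a residue list into overlapping dinucleotide steps.

    Consecutive residues form a step when both map to a parent base and
    the O3'(i)-P(i+1) distance is below the covalent-linkage cutoff;
    pairs failing either test are skipped with a logged reason.  A chain
    of n linked nucleotides yields n-1 steps.
    """
    nucs: list[NucleotideResidue | None] = []
    for res in chain:
        if isinstance(res, NucleotideResidue):
            nucs.append(res)
        else:
            nucs.append(NucleotideResidue.from_residue(res, mapping))
    steps = []
    for i in range(len(nucs) - 1):
        a, b = nucs[i], nucs[i + 1]
        if a is None or b is None:
            logger.debug("skip pair %d: unmapped residue name", i)
            continue
        o3 = a.atom("O3'")
        p = b.atom("P")
        if o3 is None or p is None:
            logger.debug("skip pair %d: missing O3'/P", i)
            continue
        if np.linalg.norm(o3.position - p.position) > linkage_cutoff:
            logger.debug("skip pair %d: chain break (O3'-P > %.1f A)", i, linkage_cutoff)
            continue
        steps.append(DinucleotideStep(first=a, second=b,
                                      source=(structure_id, a.chain_id, a.number)))
    return steps


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Torsion angle of four points, degrees in [0, 360)."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("degenerate (collinear) geometry: torsion undefined")
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = np.degrees(np.arctan2(y, x))
    return ang % 360.0


@dataclass
class TorsionVector:
    """The nine step torsions (degrees, [0, 360)); NaN marks undefined angles."""

    values: np.ndarray  # length 9, ordered as TORSION_NAMES

    @property
    def complete(self) -> bool:
        return bool(np.all(np.isfinite(self.values)))


def _glyco_atoms(res: NucleotideResidue) -> tuple[str, str]:
    return _PURINE_GLYCO if res.one_letter in _PURINES else _PYRIMIDINE_GLYCO


def step_torsions(step: DinucleotideStep) -> TorsionVector:
    """Compute the nine-torsion fingerprint of a step.

    delta/epsilon/zeta of residue i, alpha/beta/gamma/delta of residue
    i+1, and the two glycosidic chi angles.  Angles whose atoms are
    missing come back as NaN and mark the vector incomplete.
    """
    r1, r2 = step.first, step.second
    n1, c1 = _glyco_atoms(r1)
    n2, c2 = _glyco_atoms(r2)
    defs = {
        "delta1": [(r1, "C5'"), (r1, "C4'"), (r1, "C3'"), (r1, "O3'")],
        "epsilon1": [(r1, "C4'"), (r1, "C3'"), (r1, "O3'"), (r2, "P")],
        "zeta1": [(r1, "C3'"), (r1, "O3'"), (r2, "P"), (r2, "O5'")],
        "alpha2": [(r1, "O3'"), (r2, "P"), (r2, "O5'"), (r2, "C5'")],
        "beta2": [(r2, "P"), (r2, "O5'"), (r2, "C5'"), (r2, "C4'")],
        "gamma2": [(r2, "O5'"), (r2, "C5'"), (r2, "C4'"), (r2, "C3'")],
        "delta2": [(r2, "C5'"), (r2, "C4'"), (r2, "C3'"), (r2, "O3'")],
        "chi1": [(r1, "O4'"), (r1, "C1'"), (r1, n1), (r1, c1)],
        "chi2": [(r2, "O4'"), (r2, "C1'"), (r2, n2), (r2, c2)],
    }
    vals = np.full(9, np.nan)
    for k, name in enumerate(TORSION_NAMES):
        atoms = [res.atom(an) for res, an in defs[name]]
        if any(a is None for a in atoms):
            continue
        try:
            vals[k] = dihedral(*[a.position for a in atoms])
        except ValueError:
            pass  # collinear: leave NaN
    return TorsionVector(values=vals)


@dataclass
class ClassifierTable:
    """Conformer-label source: torsion centroids and/or explicit assignments.

    ``centroids`` maps NtC label -> 9-torsion centroid (degrees);
    ``assignments`` maps (structure_id, chain_id, residue_number) of a
    step's first residue -> NtC label.
    """

    centroids: dict[str, np.ndarray] = field(default_factory=dict)
    assignments: dict[tuple[str, str, int], str] = field(default_factory=dict)

    @classmethod
    def read_centroids(cls, path: str | Path) -> "ClassifierTable":
        df = pd.read_csv(path, sep="\t")
        centroids = {}
        for _, row in df.iterrows():
            centroids[str(row["ntc"])] = np.array([float(row[t]) for t in TORSION_NAMES])
        return cls(centroids=centroids)

    @classmethod
    def read_assignments(cls, path: str | Path) -> "ClassifierTable":
        df = pd.read_csv(path, sep="\t")
        assignments = {}
        for _, row in df.iterrows():
            key = (str(row["structure_id"]), str(row["chain_id"]), int(row["residue_number"]))
            assignments[key] = str(row["ntc"])
        return cls(assignments=assignments)

    def write_centroids(self, path: str | Path) -> None:
        rows = [{"ntc": ntc, **dict(zip(TORSION_NAMES, map(float, v)))}
                for ntc, v in self.centroids.items()]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _wrapped_diff(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-angle circular difference in (-180, 180]."""
    d = (a - b) % 360.0
    return np.where(d > 180.0, d - 360.0, d)


#: Per-vector Euclidean rejection radius of the nearest-centroid
#: classifier (degrees); beyond it a step is NANT.
DEFAULT_REJECTION_RADIUS = 60.0


def assign_ntc(step: DinucleotideStep, table: ClassifierTable, mode: str = "lookup",
               rejection_radius: float = DEFAULT_REJECTION_RADIUS) -> str:
    """Assign an NtC conformer label to a step.

    ``lookup`` consults the external assignment table keyed by the
    step's source (NANT when absent).  ``nearest-centroid`` picks the
    centroid minimizing the circular Euclidean distance over the nine
    torsions, with NANT beyond the rejection radius; ties go to the
    label earliest in the fixed vocabulary order.
    """
    if mode == "lookup":
        return table.assignments.get(step.source, NANT)
    if mode != "nearest-centroid":
        raise ValueError(f"unknown mode {mode!r}")
    tv = step_torsions(step)
    if not tv.complete:
        logger.info("step %s: incomplete torsion vector -> NANT", step.source)
        return NANT
    best_label, best_dist = NANT, np.inf
    order = {lab: i for i, lab in enumerate(NTC_VOCABULARY)}
    for label in sorted(table.centroids, key=lambda l: order.get(l, len(order))):
        d = float(np.linalg.norm(_wrapped_diff(tv.values, table.centroids[label])))
        if d < best_dist - 1e-12:
            best_label, best_dist = label, d
    if best_dist > rejection_radius:
        return NANT
    return best_label


def select_reference(steps: list[DinucleotideStep],
                     class_representative: dict[str, np.ndarray]) -> DinucleotideStep:
    """Pick the step with lowest superposed r.m.s.d. to the class representative.

    The r.m.s.d. uses the Kabsch superposition over heavy-atom labels
    shared with the representative; ties within 1e-4 A are broken by
    input order.
    """
    from .blocks import kabsch_superpose  # local import to avoid a cycle

    if not steps:
        raise ValueError("no candidate steps")
    combos = {(s.ntc, s.seq2) for s in steps}
    if len(combos) > 1:
        raise ValueError(f"mixed NtC/sequence combinations: {combos}")
    best, best_rmsd = None, np.inf
    for s in steps:
        coords = s.labeled_coords()
        shared = sorted(set(coords) & set(class_representative))
        if len(shared) < 3:
            continue
        mov = np.stack([coords[k] for k in shared])
        tgt = np.stack([class_representative[k] for k in shared])
        _, _, rmsd = kabsch_superpose(mov, tgt)
        if rmsd < best_rmsd - 1e-4:
            best, best_rmsd = s, rmsd
    if best is None:
        raise ValueError("no step shares >= 3 atoms with the representative")
    return best
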