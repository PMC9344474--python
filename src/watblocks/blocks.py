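"""Hydrated building blocks.

Waters within d_assoc = 4.0 A of a dinucleotide step are associated
with it, then transferred into the frame of the reference dinucleotide
of that step's NtC/sequence combination by superposing the six step
atoms nearest the water onto their named counterparts in the
reference.  The accumulated water ensemble plus the reference
coordinates form a hydrated building block.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fragments import DinucleotideStep
from .structure_io import AtomRecord

logger = logging.getLogger(__name__)


@dataclass
class AssociationParams:
    """Distance and reliability parameters of block building.

    d_assoc: water-to-dinucleotide association cutoff (A).
    d_calc: base/backbone category cutoff used for the densities (A).
    r_occ: radius used to count waters supporting a hydration site (A).
    min_waters_reliable: minimum associated waters for a combination to
        be considered reliable.
    transfer_rmsd_max: six-atom superposition r.m.s.d. above which a
        water transfer is rejected (quality gate; distorted local
        frames would smear the density).
    """

    d_assoc: float = 4.0
    d_calc: float = 3.4
    r_occ: float = 1.0
    min_waters_reliable: int = 800
    transfer_rmsd_max: float = 0.75

    def __post_init__(self) -> None:
        if not (0 < self.d_calc <= self.d_assoc):
            raise ValueError("require 0 < d_calc <= d_assoc")
        if self.r_occ <= 0:
            raise ValueError("r_occ must be positive")


@dataclass
class AssociatedWater:
    """A water tied to one step, with category flags and transfer metadata."""

    position: np.ndarray
    source_id: str
    near_base: bool
    near_backbone: bool
    nearest_distance: float
    weight: float = 1.0
    transfer_rmsd: float = 0.0


def kabsch_superpose(moving: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of paired point sets.

    Returns ``(R, t, rmsd)`` with ``R`` a proper rotation (det +1,
    reflections forbidden) and ``t`` such that ``moving @ R.T + t``
    best fits ``target``.
    """
    moving = np.asarray(moving, dtype=float)
    target = np.asarray(target, dtype=float)
    if moving.shape != target.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValueError("point sets must be matched (n, 3) arrays")
    n = moving.shape[0]
    if n < 3:
        raise ValueError("need at least 3 point pairs")
    mc = moving.mean(axis=0)
    tc = target.mean(axis=0)
    A = moving - mc
    B = target - tc
    H = A.T @ B
    U, S, Vt = np.linalg.svd(H)
    # degenerate if the two smallest singular values vanish (collinear)
    if S[1] < 1e-9 * max(S[0], 1e-30):
        raise ValueError("degenerate superposition: points are (near-)collinear")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ mc
    diff = A @ R.T - B
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return R, t, rmsd


def associate_waters(step: DinucleotideStep, waters: list[AtomRecord],
                     params: AssociationParams | None = None) -> list[AssociatedWater]:
    """Associate waters lying within d_assoc of any heavy atom of the step.

    Category flags record whether the water is within d_calc of a base
    atom and/or a backbone atom of either residue; a water may carry
    both flags, one, or neither (associated via 3.4-4.0 A contacts
    only).  A water may independently associate with several
    overlapping steps.
    """
    params = params or AssociationParams()
    if not waters:
        return []
    atoms = [a for _, a in step.heavy_atoms()]
    coords = np.stack([a.position for a in atoms])
    base_coords = np.stack([a.position for a in step.base_atoms()]) if step.base_atoms() else None
    bb_coords = np.stack([a.position for a in step.backbone_atoms()]) if step.backbone_atoms() else None

    wpos = np.stack([w.position for w in waters])
    d_all = np.linalg.norm(wpos[:, None, :] - coords[None, :, :], axis=2)
    dmin = d_all.min(axis=1)

    out = []
    for i, w in enumerate(waters):
        if dmin[i] >= params.d_assoc:
            continue
        db = np.min(np.linalg.norm(w.position - base_coords, axis=1)) if base_coords is not None else np.inf
        dk = np.min(np.linalg.norm(w.position - bb_coords, axis=1)) if bb_coords is not None else np.inf
        wid = f"{w.structure_id}/{w.chain_id}/{w.residue_number}"
        if w.sym_op is not None:
            wid += f"@{w.sym_op}{w.sym_shift}"
        out.append(AssociatedWater(
            position=np.asarray(w.position, float),
            source_id=wid,
            near_base=db <= params.d_calc,
            near_backbone=dk <= params.d_calc,
            nearest_distance=float(dmin[i]),
        ))
    return out


def _six_nearest(step: DinucleotideStep, water_pos: np.ndarray,
                 reference_labels: set[str]) -> list[str]:
    """Labels of the six step atoms nearest the water that exist in the reference.

    Ties at equal distance are broken by (residue position, atom name)
    so the selection is deterministic.
    """
    labeled = step.heavy_atoms()
    cand = []
    for lab, atom in labeled:
        if lab not in reference_labels:
            continue
        d = float(np.linalg.norm(atom.position - water_pos))
        cand.append((d, lab))
    cand.sort(key=lambda t: (t[0], t[1]))
    return [lab for _, lab in cand[:6]]


def transfer_water(water: AssociatedWater, source_step: DinucleotideStep,
                   reference: dict[str, np.ndarray],
                   params: AssociationParams | None = None) -> AssociatedWater | None:
    """Transfer a water into the reference frame via six-nearest-atom alignment.

    The six source-step heavy atoms nearest the water (restricted to
    names present in the reference) are superposed onto their reference
    counterparts; the resulting rigid transform moves the water.
    Returns ``None`` (logged) when fewer than six atoms can be matched,
    the local frame is degenerate, or the six-atom r.m.s.d. exceeds the
    acceptance threshold.
    """
    params = params or AssociationParams()
    labels = _six_nearest(source_step, water.position, set(reference))
    if len(labels) < 6:
        logger.debug("water %s: only %d matchable atoms, dropped", water.source_id, len(labels))
        return None
    coords = source_step.labeled_coords()
    mov = np.stack([coords[l] for l in labels])
    tgt = np.stack([reference[l] for l in labels])
    try:
        R, t, rmsd = kabsch_superpose(mov, tgt)
    except ValueError:
        logger.debug("water %s: degenerate six-atom frame, dropped", water.source_id)
        return None
    if rmsd > params.transfer_rmsd_max:
        logger.debug("water %s: transfer rmsd %.2f above threshold, dropped",
                     water.source_id, rmsd)
        return None
    new_pos = R @ water.position + t
    return AssociatedWater(
        position=new_pos,
        source_id=water.source_id,
        near_base=water.near_base,
        near_backbone=water.near_backbone,
        nearest_distance=water.nearest_distance,
        weight=water.weight,
        transfer_rmsd=rmsd,
    )


@dataclass
class HydratedBlock:
    """Reference dinucleotide of one NtC/sequence combination plus its waters."""

    ntc: str
    seq2: str
    reference: dict[str, np.ndarray]
    waters: list[AssociatedWater]
    n_steps: int
    min_waters_reliable: int = 800

    @property
    def n_waters(self) -> int:
        return len(self.waters)

    @property
    def reliable(self) -> bool:
        return self.n_waters >= self.min_waters_reliable


def medoid_step(steps: list[DinucleotideStep]) -> DinucleotideStep:
    """The step minimizing summed pairwise superposed r.m.s.d. (used as
    reference when no external class representative is supplied)."""
    if not steps:
        raise ValueError("no steps")
    if len(steps) == 1:
        return steps[0]
    coords = [s.labeled_coords() for s in steps]
    n = len(steps)
    total = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            shared = sorted(set(coords[i]) & set(coords[j]))
            if len(shared) < 3:
                continue
            a = np.stack([coords[i][k] for k in shared])
            b = np.stack([coords[j][k] for k in shared])
            _, _, rmsd = kabsch_superpose(a, b)
            total[i] += rmsd
            total[j] += rmsd
    return steps[int(np.argmin(total))]


def build_block(ntc: str, seq2: str,
                hydrated_steps: list[tuple[DinucleotideStep, list[AssociatedWater]]],
                reference: DinucleotideStep | dict[str, np.ndarray] | None = None,
                params: AssociationParams | None = None) -> HydratedBlock:
    """Assemble the hydrated building block of one NtC/sequence combination.

    Transfers every associated water of every contributing step onto
    the reference coordinates; per-water weights start at 1 so that
    prediction-time scaling is a pure reweighting.
    """
    params = params or AssociationParams()
    for step, _ in hydrated_steps:
        if (step.ntc, step.seq2) != (ntc, seq2):
            raise ValueError(f"step {step.source} is {(step.ntc, step.seq2)}, "
                             f"expected {(ntc, seq2)}")
    if reference is None:
        if not hydrated_steps:
            return HydratedBlock(ntc=ntc, seq2=seq2, reference={}, waters=[],
                                 n_steps=0, min_waters_reliable=params.min_waters_reliable)
        reference = medoid_step([s for s, _ in hydrated_steps])
    if isinstance(reference, DinucleotideStep):
        reference = reference.labeled_coords()

    transferred: list[AssociatedWater] = []
    for step, assoc in hydrated_steps:
        for w in assoc:
            tw = transfer_water(w, step, reference, params)
            if tw is not None:
                transferred.append(tw)
    return HydratedBlock(ntc=ntc, seq2=seq2, reference=reference,
                         waters=transferred, n_steps=len(hydrated_steps),
                         min_waters_reliable=params.min_waters_reliable)


@dataclass
class BlockLibrary:
    """All hydrated building blocks of a corpus, keyed by (NtC, seq2)."""

    blocks: dict[tuple[str, str], HydratedBlock] = field(default_factory=dict)
    params: AssociationParams = field(default_factory=AssociationParams)
    provenance: dict = field(default_factory=dict)

    def add(self, block: HydratedBlock) -> None:
        key = (block.ntc, block.seq2)
        if key in self.blocks:
            raise ValueError(f"duplicate block for combination {key}")
        self.blocks[key] = block

    def get(self, ntc: str, seq2: str) -> HydratedBlock | None:
        return self.blocks.get((ntc, seq2))

    # ---- persistence: one reference PDB + one water TSV per block ----

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "params": {
                "d_assoc": self.params.d_assoc,
                "d_calc": self.params.d_calc,
                "r_occ": self.params.r_occ,
                "min_waters_reliable": self.params.min_waters_reliable,
                "transfer_rmsd_max": self.params.transfer_rmsd_max,
            },
            "provenance": self.provenance,
            "blocks": [],
        }
        for (ntc, seq2), block in sorted(self.blocks.items()):
            stem = f"{ntc}_{seq2}"
            _write_reference_pdb(block.reference, directory / f"{stem}_ref.pdb")
            rows = [{
                "x": w.position[0], "y": w.position[1], "z": w.position[2],
                "near_base": int(w.near_base), "near_backbone": int(w.near_backbone),
                "weight": w.weight, "transfer_rmsd": w.transfer_rmsd,
                "source": w.source_id,
            } for w in block.waters]
            pd.DataFrame(rows, columns=["x", "y", "z", "near_base", "near_backbone",
                                        "weight", "transfer_rmsd", "source"]
                         ).to_csv(directory / f"{stem}_waters.tsv", sep="\t", index=False)
            manifest["blocks"].append({
                "ntc": ntc, "seq2": seq2, "n_steps": block.n_steps,
                "n_waters": block.n_waters, "reliable": block.reliable,
            })
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    @classmethod
    def load(cls, directory: str | Path) -> "BlockLibrary":
        directory = Path(directory)
        manifest_path = directory / "manifest.json"
        if not manifest_path.exists():
            raise FileNotFoundError(f"no manifest.json in {directory}")
        try:
            manifest = json.loads(manifest_path.read_text())
            entries = manifest["blocks"]
            p = manifest["params"]
        except (json.JSONDecodeError, KeyError) as exc:
            raise ValueError(f"malformed library manifest in {directory}: {exc}") from exc
        params = AssociationParams(**p)
        lib = cls(params=params, provenance=manifest.get("provenance", {}))
        for entry in entries:
            ntc, seq2 = entry["ntc"], entry["seq2"]
            stem = f"{ntc}_{seq2}"
            reference = _read_reference_pdb(directory / f"{stem}_ref.pdb")
            df = pd.read_csv(directory / f"{stem}_waters.tsv", sep="\t")
            waters = [AssociatedWater(
                position=np.array([r.x, r.y, r.z]),
                source_id=str(r.source),
                near_base=bool(r.near_base),
                near_backbone=bool(r.near_backbone),
                nearest_distance=np.nan,
                weight=float(r.weight),
                transfer_rmsd=float(r.transfer_rmsd),
            ) for r in df.itertuples()]
            lib.add(HydratedBlock(ntc=ntc, seq2=seq2, reference=reference,
                                  waters=waters, n_steps=int(entry["n_steps"]),
                                  min_waters_reliable=params.min_waters_reliable))
        return lib


def _write_reference_pdb(reference: dict[str, np.ndarray], path: Path) -> None:
    """Reference coordinates as a two-residue PDB file; the residue slot
    is encoded in the residue number."""
    lines = []
    serial = 1
    for label in sorted(reference, key=lambda l: (l.split(":")[0], l.split(":")[1])):
        slot, name = label.split(":", 1)
        x, y, z = reference[label]
        el = name[0] if name[0].isalpha() else name[1]
        pdb_name = name if len(name) >= 4 else f" {name:<3s}"
        lines.append(
            f"ATOM  {serial:5d} {pdb_name:<4s} REF R{int(slot):4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {el:>2s}"
        )
        serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def _read_reference_pdb(path: Path) -> dict[str, np.ndarray]:
    reference = {}
    for line in path.read_text().splitlines():
        if not line.startswith(("ATOM", "HETATM")):
            continue
        name = line[12:16].strip()
        slot = line[22:26].strip()
        xyz = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
        reference[f"{slot}:{name}"] = xyz
    return reference
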