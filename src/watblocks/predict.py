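"""Whole-structure hydration prediction and evaluation.

Each dinucleotide step of the target structure is matched with the
hydrated building block of its NtC/sequence combination; the block's
water ensemble is superposed onto the step and accumulated — with
per-water weights inversely proportional to the block population, so
populous blocks do not outweigh sparse ones — into global base and
backbone density grids.  Peaks of those grids are the predicted
hydration sites, which can be scored against crystallographically
observed waters (asymmetric unit plus symmetry mates).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .blocks import (AssociationParams, AssociatedWater, BlockLibrary,
                     HydratedBlock, kabsch_superpose)
from .density import DensityParams, GridDensity, HydrationSite, find_peaks, \
    accumulate_density, site_occupancy
from .fragments import (NANT, BACKBONE_ATOMS, ClassifierTable, DinucleotideStep,
                        assign_ntc, extract_steps)
from .structure_io import AtomRecord, StructureModel

logger = logging.getLogger(__name__)


@dataclass
class StepLog:
    """Why a target step did or did not contribute to the prediction."""

    source: tuple[str, str, int]
    ntc: str
    seq2: str
    used: bool
    reason: str = ""


@dataclass
class PredictionResult:
    """Predicted hydration of one structure, split by category."""

    target_id: str
    base_grid: GridDensity | None
    backbone_grid: GridDensity | None
    base_sites: list[HydrationSite]
    backbone_sites: list[HydrationSite]
    per_step_log: list[StepLog]
    total_weight: float = 0.0

    @property
    def sites(self) -> list[HydrationSite]:
        return self.base_sites + self.backbone_sites


def overlay_block(block: HydratedBlock, target_step: DinucleotideStep) -> list[AssociatedWater]:
    """Superpose a block onto a target step and move its waters along.

    All heavy-atom labels shared between the block reference and the
    target step are used for the superposition; when fewer than three
    base-atom names match (modified bases), the backbone subset is
    tried.  Every transferred water gets weight 1 / n_steps of the
    block so block populations do not bias the overlay densities.
    """
    if (block.ntc, block.seq2) != (target_step.ntc, target_step.seq2):
        raise ValueError(
            f"block {(block.ntc, block.seq2)} does not match step "
            f"{(target_step.ntc, target_step.seq2)}")
    tcoords = target_step.labeled_coords()
    shared = sorted(set(block.reference) & set(tcoords))
    if len(shared) < 3:
        backbone_labels = [l for l in tcoords
                           if l.split(":")[1] in BACKBONE_ATOMS and l in block.reference]
        shared = sorted(backbone_labels)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared atoms between block and step")
    mov = np.stack([block.reference[l] for l in shared])
    tgt = np.stack([tcoords[l] for l in shared])
    R, t, _ = kabsch_superpose(mov, tgt)
    weight = 1.0 / block.n_steps if block.n_steps else 1.0
    out = []
    for w in block.waters:
        out.append(dataclasses.replace(
            w, position=R @ w.position + t, weight=w.weight * weight))
    return out


def predict_hydration(target: StructureModel, library: BlockLibrary,
                      classifier: ClassifierTable, classifier_mode: str = "lookup",
                      density_params: DensityParams | None = None,
                      assoc_params: AssociationParams | None = None,
                      allow_unreliable: bool = False) -> PredictionResult:
    """Predict base and backbone hydration of a whole DNA structure.

    NANT steps and combinations missing from (or unreliable in) the
    library are skipped and logged.  Waters transferred from all used
    blocks are accumulated into a single pair of global grids so
    overlapping steps reinforce shared sites; occupancies are computed
    with divisor 1 because the weights already carry 1/n_steps.
    """
    density_params = density_params or DensityParams()
    assoc_params = assoc_params or AssociationParams()
    if not library.blocks:
        raise ValueError("empty block library")

    steps: list[DinucleotideStep] = []
    for chain_id, residues in target.chains.items():
        steps.extend(extract_steps(residues, structure_id=target.structure_id))
    if not steps:
        raise ValueError(f"no extractable dinucleotide steps in {target.structure_id!r}")

    log: list[StepLog] = []
    transferred: list[AssociatedWater] = []
    total_weight = 0.0
    for step in steps:
        step.ntc = assign_ntc(step, classifier, mode=classifier_mode)
        if step.ntc == NANT:
            log.append(StepLog(step.source, NANT, step.seq2, False, "NANT step"))
            continue
        block = library.get(step.ntc, step.seq2)
        if block is None or block.n_waters == 0:
            log.append(StepLog(step.source, step.ntc, step.seq2, False,
                               "combination absent from library"))
            continue
        if not block.reliable and not allow_unreliable:
            log.append(StepLog(step.source, step.ntc, step.seq2, False,
                               f"unreliable block (n_waters={block.n_waters})"))
            continue
        try:
            waters = overlay_block(block, step)
        except ValueError as exc:
            log.append(StepLog(step.source, step.ntc, step.seq2, False, str(exc)))
            continue
        transferred.extend(waters)
        total_weight += block.n_waters / block.n_steps
        log.append(StepLog(step.source, step.ntc, step.seq2, True,
                           f"block {block.ntc}/{block.seq2}"))

    frame = target.dna_heavy_coords()
    base_grid = backbone_grid = None
    base_sites: list[HydrationSite] = []
    backbone_sites: list[HydrationSite] = []
    if any(e.used for e in log):
        base_waters = [w for w in transferred if w.near_base]
        bb_waters = [w for w in transferred if w.near_backbone]
        base_grid = accumulate_density(base_waters, frame, density_params, "base")
        backbone_grid = accumulate_density(bb_waters, frame, density_params, "backbone")
        thr = density_params.peak_threshold(1.0)
        for grid, waters, out in ((base_grid, base_waters, base_sites),
                                  (backbone_grid, bb_waters, backbone_sites)):
            for p in find_peaks(grid, density_params, threshold=thr):
                out.append(site_occupancy(p, waters, n_steps=1, params=assoc_params))
    else:
        logger.warning("no usable steps in %s; empty prediction", target.structure_id)

    return PredictionResult(target_id=target.structure_id,
                            base_grid=base_grid, backbone_grid=backbone_grid,
                            base_sites=base_sites, backbone_sites=backbone_sites,
                            per_step_log=log, total_weight=total_weight)


@dataclass
class EvaluationReport:
    """Nearest-observed-water distances of predicted hydration sites.

    Distances are binned in 0.5 A intervals; ``frac_within_1A`` is the
    fraction of predicted sites falling in the first two bins, i.e.
    within 1.0 A of a crystallographic water.
    """

    bin_width: float = 0.5
    distances: dict[str, np.ndarray] = field(default_factory=dict)
    histogram: dict[str, np.ndarray] = field(default_factory=dict)
    frac_within_1A: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "bin_width": self.bin_width,
            "frac_within_1A": {k: float(v) for k, v in self.frac_within_1A.items()},
            "histogram": {k: [int(c) for c in v] for k, v in self.histogram.items()},
            "n_sites": {k: int(len(v)) for k, v in self.distances.items()},
        }


def evaluate_prediction(result: PredictionResult, observed: list[AtomRecord],
                        bin_width: float = 0.5) -> EvaluationReport:
    """Score predicted sites against observed waters (incl. symmetry mates)."""
    if not observed:
        raise ValueError("no observed waters: evaluation is meaningless")
    tree = cKDTree(np.stack([w.position for w in observed]))
    report = EvaluationReport(bin_width=bin_width)
    groups = {
        "base": result.base_sites,
        "backbone": result.backbone_sites,
        "overall": result.sites,
    }
    for name, sites in groups.items():
        if sites:
            pos = np.stack([s.position for s in sites])
            d, _ = tree.query(pos)
            d = np.atleast_1d(d)
        else:
            d = np.empty(0)
        n_bins = max(int(np.floor(d.max() / bin_width)) + 1, 2) if len(d) else 2
        hist = np.array([np.sum((d >= i * bin_width) & (d < (i + 1) * bin_width))
                         for i in range(n_bins)], dtype=int)
        # the first two bins are [0, w) and [w, 2w): "within 1 A" means d < 1.0
        frac = float((hist[0] + hist[1]) / len(d)) if len(d) else float("nan")
        report.distances[name] = d
        report.histogram[name] = hist
        report.frac_within_1A[name] = frac
    return report
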