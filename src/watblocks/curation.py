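"""Corpus curation: sequence-redundancy clustering and hydration filters.

Chains enter as (structure, chain, resolution, sequence, waters per
nucleotide) rows.  Chains with the same or a similar sequence form a
sequential cluster, from which one representative is selected by
resolution and, within a 0.1 A resolution window, by water content.
Only chains of at least six nucleotides, resolution <= 2.6 A and more
than one water per nucleotide survive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_io import Residue, StructureModel, SymmetryExpansion, extract_waters

logger = logging.getLogger(__name__)


@dataclass
class ChainEntry:
    """One DNA chain of the intake table."""

    structure_id: str
    chain_id: str
    resolution: float
    sequence: str
    waters_per_nucleotide: float
    is_complexed: bool = False
    cluster_id: int | None = None

    @property
    def n_nuc(self) -> int:
        return len(self.sequence)


def _default_long_mismatch(n_nuc: int) -> int:
    # floor(N/12): continuous with the 2-mismatch rule at 24 nt
    return n_nuc // 12


@dataclass
class CurationParams:
    """Selection thresholds of the corpus curation.

    Resolution bound is inclusive (2.6 A keeps), the waters-per-
    nucleotide bound exclusive (exactly 1.0 drops).  Sequences shorter
    than ``short_seq_len`` may differ at ``short_seq_mismatches``
    positions and still be redundant; longer ones use
    ``long_mismatch_fn`` of their length.
    """

    max_resolution: float = 2.6
    min_waters_per_nt: float = 1.0
    resolution_tie_window: float = 0.1
    short_seq_len: int = 24
    short_seq_mismatches: int = 2
    long_mismatch_fn: Callable[[int], int] = _default_long_mismatch
    water_contact_cutoff: float = 3.4
    min_nuc: int = 6

    def __post_init__(self) -> None:
        if min(self.max_resolution, self.resolution_tie_window,
               self.water_contact_cutoff) <= 0:
            raise ValueError("cutoffs must be positive")
        if self.long_mismatch_fn(self.short_seq_len) < self.short_seq_mismatches:
            logger.warning("long_mismatch_fn(%d)=%d < short-sequence threshold %d: "
                           "discontinuous redundancy rule",
                           self.short_seq_len, self.long_mismatch_fn(self.short_seq_len),
                           self.short_seq_mismatches)

    def mismatch_threshold(self, n_nuc: int) -> int:
        if n_nuc < self.short_seq_len:
            return self.short_seq_mismatches
        return self.long_mismatch_fn(n_nuc)


@dataclass
class Cluster:
    """A sequential cluster of redundant chains."""

    members: list[ChainEntry] = field(default_factory=list)
    representative: ChainEntry | None = None


def waters_per_nucleotide(chain: list[Residue], model: StructureModel,
                          expansion: SymmetryExpansion | None = None,
                          cutoff: float = 3.4) -> float:
    """Distinct waters within ``cutoff`` of the chain, per nucleotide.

    Counts ASU waters plus symmetry-mate waters; an ASU water whose
    mate also qualifies is still counted once, but distinct mates of
    the same ASU water count separately (they are separate lattice
    copies touching this chain).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    nucleotides = [r for r in chain if r.is_nucleotide]
    if not nucleotides:
        raise ValueError("chain has no nucleotide residues")
    coords = np.vstack([r.heavy_coords() for r in nucleotides])
    tree = cKDTree(coords)
    waters = extract_waters(model, expansion)
    count = 0
    seen_asu: set[tuple[str, str, int]] = set()
    for w in waters:
        d, _ = tree.query(w.position)
        if d >= cutoff:
            continue
        if w.sym_op is None:
            key = (w.structure_id, w.chain_id, w.residue_number)
            if key in seen_asu:
                continue
            seen_asu.add(key)
        count += 1
    return count / len(nucleotides)


def _mismatches_equal(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _sliding_mismatches(short: str, long: str) -> int:
    """Best ungapped alignment of the shorter sequence inside the longer."""
    best = len(short)
    for off in range(len(long) - len(short) + 1):
        best = min(best, _mismatches_equal(short, long[off:off + len(short)]))
        if best == 0:
            break
    return best


def sequences_redundant(a: str, b: str, params: CurationParams) -> bool:
    """Do two sequences belong to the same sequential cluster?"""
    if len(a) == len(b):
        return _mismatches_equal(a, b) <= params.mismatch_threshold(len(a))
    short, long = (a, b) if len(a) < len(b) else (b, a)
    return _sliding_mismatches(short, long) <= params.mismatch_threshold(len(short))


def cluster_chains(entries: list[ChainEntry],
                   params: CurationParams | None = None) -> list[Cluster]:
    """Single-linkage clustering of chains by sequence redundancy.

    Clusters are the transitive closure of the pairwise redundancy
    relation.  Cluster ids are assigned in order of the
    lexicographically smallest (structure_id, chain_id) member, so the
    numbering is independent of input order.
    """
    params = params or CurationParams()
    n = len(entries)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if sequences_redundant(entries[i].sequence, entries[j].sequence, params):
                parent[find(i)] = find(j)

    groups: dict[int, list[ChainEntry]] = {}
    for i, e in enumerate(entries):
        groups.setdefault(find(i), []).append(e)
    clusters = sorted(groups.values(),
                      key=lambda ms: min((m.structure_id, m.chain_id) for m in ms))
    out = []
    for cid, members in enumerate(clusters):
        for m in members:
            m.cluster_id = cid
        out.append(Cluster(members=members))
    return out


def select_representative(cluster: Cluster,
                          params: CurationParams | None = None) -> ChainEntry:
    """Pick the cluster representative.

    Best resolution wins; among entries within the resolution tie
    window of the best, the highest waters-per-nucleotide wins; any
    remaining tie goes to the lexicographically smallest
    (structure_id, chain_id).
    """
    params = params or CurationParams()
    if not cluster.members:
        raise ValueError("empty cluster")
    best_res = min(m.resolution for m in cluster.members)
    window = [m for m in cluster.members
              if m.resolution <= best_res + params.resolution_tie_window]
    rep = min(window, key=lambda m: (-m.waters_per_nucleotide,
                                     m.structure_id, m.chain_id))
    cluster.representative = rep
    return rep


def filter_chains(entries: list[ChainEntry],
                  params: CurationParams | None = None) -> list[ChainEntry]:
    """Keep chains passing the resolution, hydration and length filters."""
    params = params or CurationParams()
    return [e for e in entries
            if e.resolution <= params.max_resolution
            and e.waters_per_nucleotide > params.min_waters_per_nt
            and e.n_nuc >= params.min_nuc]


def curate(entries: list[ChainEntry],
           params: CurationParams | None = None) -> list[ChainEntry]:
    """Full pipeline: filter, cluster, select one representative per cluster."""
    params = params or CurationParams()
    kept = filter_chains(entries, params)
    clusters = cluster_chains(kept, params)
    return [select_representative(c, params) for c in clusters]


# ---- CSV table I/O -------------------------------------------------------

_COLUMNS = ["structure_id", "chain_id", "resolution", "sequence",
            "n_nuc", "waters_per_nucleotide", "is_complexed", "cluster_id"]


def write_chain_table(entries: list[ChainEntry], path: str | Path) -> None:
    rows = [{
        "structure_id": e.structure_id, "chain_id": e.chain_id,
        "resolution": e.resolution, "sequence": e.sequence, "n_nuc": e.n_nuc,
        "waters_per_nucleotide": e.waters_per_nucleotide,
        "is_complexed": int(e.is_complexed),
        "cluster_id": -1 if e.cluster_id is None else e.cluster_id,
    } for e in entries]
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


def read_chain_table(path: str | Path) -> list[ChainEntry]:
    df = pd.read_csv(path)
    entries = []
    for r in df.itertuples():
        cid = int(getattr(r, "cluster_id", -1))
        entries.append(ChainEntry(
            structure_id=str(r.structure_id), chain_id=str(r.chain_id),
            resolution=float(r.resolution), sequence=str(r.sequence),
            waters_per_nucleotide=float(r.waters_per_nucleotide),
            is_complexed=bool(getattr(r, "is_complexed", False)),
            cluster_id=None if cid < 0 else cid))
    return entries
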