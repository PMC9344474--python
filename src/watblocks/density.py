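"""Water probability densities and hydration sites.

Weighted water point sets are turned into smooth probability densities
by accumulating normalized, truncated isotropic Gaussians on a
Cartesian grid — a band-limited kernel sum playing the role of the
crystallographic Fourier-averaging procedure, with the kernel width
sigma standing in for the pseudo-atom form-factor width.  Hydration
sites are local density maxima; their occupancy is the summed weight
of waters within r_occ of the peak divided by the number of
contributing dinucleotides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .blocks import AssociationParams, AssociatedWater

logger = logging.getLogger(__name__)


@dataclass
class DensityParams:
    """Grid and peak-picking parameters.

    spacing: voxel edge (A).
    sigma: isotropic Gaussian width per water (A); warn when below
        spacing/2 (undersampled kernel).
    margin: padding of the grid around the frame atoms (A); the kernel
        truncation radius (4 sigma) is added internally so edge waters
        keep their full mass.
    peak_min_separation: peaks closer than this are merged, keeping the
        higher one (A).
    min_weight: peak detection threshold expressed in
        occupancy-equivalent units — a candidate peak must reach the
        central density of a point mass of weight min_weight x scale,
        where scale is the occupancy divisor of the pipeline (n_steps
        for block analysis, 1 at prediction time).
    """

    spacing: float = 0.2
    sigma: float = 0.4
    margin: float = 4.0
    peak_min_separation: float = 1.0
    min_weight: float = 0.05

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.sigma < self.spacing / 2:
            logger.warning("sigma %.2f < spacing/2: kernel undersampled", self.sigma)
        if self.peak_min_separation < self.spacing:
            raise ValueError("peak_min_separation must be >= spacing")

    @property
    def peak_height_unit(self) -> float:
        """Central density of a unit-weight point water."""
        return (2 * np.pi * self.sigma ** 2) ** -1.5

    def peak_threshold(self, scale: float = 1.0) -> float:
        return self.min_weight * scale * self.peak_height_unit


@dataclass
class GridDensity:
    """A 3D Cartesian scalar grid of water probability density.

    Each input water of weight w contributes a Gaussian of total
    integral w, so sum(values) * spacing^3 equals the total input
    weight up to kernel truncation.
    """

    origin: np.ndarray
    spacing: float
    values: np.ndarray
    category: str = ""

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_center(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(idx, float) * self.spacing

    def total_weight(self) -> float:
        return float(self.values.sum() * self.spacing ** 3)


@dataclass
class HydrationSite:
    """A density peak interpreted as a preferred water position."""

    position: np.ndarray
    peak_value: float
    occupancy: float
    category: str
    n_support: int


def accumulate_density(waters: list[AssociatedWater], frame_atoms: np.ndarray,
                       params: DensityParams | None = None,
                       category: str = "") -> GridDensity:
    """Accumulate weighted truncated-Gaussian kernels on a grid.

    The grid covers the bounding box of ``frame_atoms`` inflated by
    ``margin`` plus the 4-sigma kernel radius.  The caller is
    responsible for passing only waters of the requested category
    (base/backbone flags are set at association time from the 3.4 A
    criterion).
    """
    params = params or DensityParams()
    frame_atoms = np.asarray(frame_atoms, dtype=float)
    if frame_atoms.size == 0:
        raise ValueError("no frame atoms: grid extent undefined")
    pad = params.margin + 4 * params.sigma
    lo = frame_atoms.min(axis=0) - pad
    hi = frame_atoms.max(axis=0) + pad
    dims = np.maximum(np.ceil((hi - lo) / params.spacing).astype(int) + 1, 1)
    values = np.zeros(dims, dtype=float)
    grid = GridDensity(origin=lo, spacing=params.spacing, values=values, category=category)
    if waters:
        positions = np.stack([w.position for w in waters])
        weights = np.array([w.weight for w in waters], dtype=float)
        _add_gaussians(grid, positions, weights, params.sigma)
    return grid


def _add_gaussians(grid: GridDensity, positions: np.ndarray, weights: np.ndarray,
                   sigma: float) -> None:
    """Add normalized isotropic Gaussians truncated at 4 sigma."""
    sp = grid.spacing
    trunc = 4.0 * sigma
    rvox = int(np.ceil(trunc / sp))
    norm = (2 * np.pi * sigma ** 2) ** -1.5
    dims = np.array(grid.values.shape)
    offsets = np.arange(-rvox, rvox + 1)
    for pos, w in zip(positions, weights):
        c = (pos - grid.origin) / sp
        c0 = np.round(c).astype(int)
        ix = c0[0] + offsets
        iy = c0[1] + offsets
        iz = c0[2] + offsets
        mx = (ix >= 0) & (ix < dims[0])
        my = (iy >= 0) & (iy < dims[1])
        mz = (iz >= 0) & (iz < dims[2])
        if not (mx.any() and my.any() and mz.any()):
            continue
        ix, iy, iz = ix[mx], iy[my], iz[mz]
        dx = ix * sp + grid.origin[0] - pos[0]
        dy = iy * sp + grid.origin[1] - pos[1]
        dz = iz * sp + grid.origin[2] - pos[2]
        r2 = (dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2)
        kern = np.where(r2 <= trunc ** 2, np.exp(-r2 / (2 * sigma ** 2)), 0.0)
        grid.values[np.ix_(ix, iy, iz)] += w * norm * kern


def find_peaks(grid: GridDensity, params: DensityParams | None = None,
               threshold: float | None = None) -> list[HydrationSite]:
    """Detect density peaks: strict 26-neighbourhood local maxima.

    Candidates at or above the threshold are refined to sub-voxel
    positions by per-axis quadratic interpolation, then greedily merged
    (descending value) when closer than ``peak_min_separation``.
    Returns sites sorted by descending peak value, with occupancy and
    support left unset (zero) — see :func:`site_occupancy`.
    """
    params = params or DensityParams()
    if threshold is None:
        threshold = params.peak_threshold()
    v = grid.values
    if v.size == 0 or v.max() < threshold:
        return []
    footprint = np.ones((3, 3, 3), dtype=bool)
    footprint[1, 1, 1] = False
    neigh_max = ndimage.maximum_filter(v, footprint=footprint, mode="constant", cval=-np.inf)
    cand = np.argwhere((v > neigh_max) & (v >= threshold))

    peaks = []
    for idx in cand:
        pos = grid.voxel_center(idx).astype(float).copy()
        val = float(v[tuple(idx)])
        for ax in range(3):
            i = idx[ax]
            if 0 < i < v.shape[ax] - 1:
                lo_idx = idx.copy(); lo_idx[ax] -= 1
                hi_idx = idx.copy(); hi_idx[ax] += 1
                y0, y1, y2 = v[tuple(lo_idx)], val, v[tuple(hi_idx)]
                denom = y0 - 2 * y1 + y2
                if denom < 0:
                    pos[ax] += 0.5 * (y0 - y2) / denom * grid.spacing
        peaks.append((val, pos))
    peaks.sort(key=lambda p: -p[0])

    kept: list[tuple[float, np.ndarray]] = []
    for val, pos in peaks:
        if all(np.linalg.norm(pos - kp) >= params.peak_min_separation for _, kp in kept):
            kept.append((val, pos))
    return [HydrationSite(position=pos, peak_value=val, occupancy=0.0,
                          category=grid.category, n_support=0)
            for val, pos in kept]


def site_occupancy(peak: np.ndarray | HydrationSite, waters: list[AssociatedWater],
                   n_steps: int, params: AssociationParams | None = None,
                   category: str = "") -> HydrationSite:
    """Occupancy of a hydration site.

    Summed weight of waters within r_occ of the peak (boundary
    inclusive) divided by the number of contributing dinucleotides.
    Occupancies above 1 (merged dense clusters) are reported, not
    clamped, with a warning.
    """
    params = params or AssociationParams()
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if isinstance(peak, HydrationSite):
        pos, val, category = np.asarray(peak.position, float), peak.peak_value, peak.category
    else:
        pos, val = np.asarray(peak, dtype=float), 0.0
    if waters:
        wpos = np.stack([w.position for w in waters])
        d = np.linalg.norm(wpos - pos, axis=1)
        sel = d <= params.r_occ
        occ = float(sum(w.weight for w, s in zip(waters, sel) if s)) / n_steps
        n_support = int(sel.sum())
    else:
        occ, n_support = 0.0, 0
    if occ > 1.0:
        logger.warning("site at %s has occupancy %.2f > 1 (merged cluster?)", pos, occ)
    return HydrationSite(position=pos, peak_value=val, occupancy=occ,
                         category=category, n_support=n_support)


def hydration_sites(waters: list[AssociatedWater], frame_atoms: np.ndarray,
                    n_steps: int, category: str,
                    density_params: DensityParams | None = None,
                    assoc_params: AssociationParams | None = None,
                    threshold_scale: float | None = None) -> tuple[GridDensity, list[HydrationSite]]:
    """Density + peak + occupancy pipeline for one water category.

    ``threshold_scale`` defaults to ``n_steps`` so the detection
    threshold is expressed in occupancy units regardless of block
    population.
    """
    density_params = density_params or DensityParams()
    assoc_params = assoc_params or AssociationParams()
    if threshold_scale is None:
        threshold_scale = float(n_steps)
    grid = accumulate_density(waters, frame_atoms, density_params, category)
    raw = find_peaks(grid, density_params,
                     threshold=density_params.peak_threshold(threshold_scale))
    sites = [site_occupancy(p, waters, n_steps, assoc_params) for p in raw]
    return grid, sites
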