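"""Synthetic two-channel tissue images with exact instance ground truth.

The generator emulates the content of multiplexed-immunofluorescence tissue
fields imaged with a nuclear marker (e.g. Hoechst/DRAQ5) and a cell-membrane
marker (e.g. Na+K+ATPase): convex-to-mildly-nonconvex elliptical nuclei with
radial intensity falloff and per-cell brightness jitter, membrane rings
around each cell (complete, partial, weak or absent), touching nucleus
pairs/triples sharing membrane walls, occasional membrane rings with no
nucleus, and additive Gaussian background noise. Ground-truth nucleus and
cell instance labels are exact by construction and every run is fully
determined by the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi

from .core_io import TwoChannelImage

logger = logging.getLogger("unseg")

__all__ = ["FixtureSpec", "FixtureBundle", "generate_tissue", "generate_cluster"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic tissue field.

    Fractions are of ``n_cells``; ``touching_fraction`` is the fraction of
    nuclei placed in abutting pairs and ``triple_fraction`` in abutting
    chains of three. Radii are nucleus semi-axes in pixels; each cell's
    membrane ring sits ``membrane_gap`` pixels beyond its nucleus and is
    ``membrane_width`` pixels wide, with ``membrane_completeness`` of its
    circumference actually drawn.
    """

    shape: tuple[int, int] = (512, 512)
    n_cells: int = 60
    radius_range: tuple[float, float] = (8.0, 13.0)
    eccentricity_range: tuple[float, float] = (1.0, 1.4)
    touching_fraction: float = 0.0
    triple_fraction: float = 0.0
    membrane_gap: int = 3
    membrane_width: int = 3
    membrane_completeness: float = 0.95
    membrane_free_fraction: float = 0.0
    nucleus_free_fraction: float = 0.0
    nucleus_peak_range: tuple[float, float] = (0.7, 0.95)
    membrane_peak_range: tuple[float, float] = (0.5, 0.9)
    falloff: float = 0.5
    intensity_jitter: float = 0.05
    blur_sigma: float = 2.0
    noise_std: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("touching_fraction", "triple_fraction",
                     "membrane_completeness", "membrane_free_fraction",
                     "nucleus_free_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.radius_range[0] < 3:
            raise ValueError("nucleus radii must be at least 3 px")

    def replace(self, **kwargs) -> "FixtureSpec":
        return replace(self, **kwargs)


@dataclass
class FixtureBundle:
    """A generated image with its exact ground truth."""

    image: TwoChannelImage
    gt_nuclei: np.ndarray
    gt_cells: np.ndarray
    spec: FixtureSpec
    membrane_free_ids: list[int] = field(default_factory=list)
    nucleus_free_cell_ids: list[int] = field(default_factory=list)


@dataclass
class _Cell:
    center: np.ndarray           # (row, col), float
    axes: np.ndarray             # nucleus semi-axes (a, b)
    theta: float                 # orientation, radians
    nucleus_peak: float
    membrane_peak: float
    has_nucleus: bool = True
    has_membrane: bool = True
    arc_kept: tuple[tuple[float, float], ...] = ()  # kept angular intervals

    def outer_axes(self, gap: int, width: int) -> np.ndarray:
        return self.axes + gap + width


def _elliptical_radius(shape: tuple[int, int], cell: _Cell) -> np.ndarray:
    """Normalized elliptical radius field (1 on the nucleus boundary)."""
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]]
    dr = rows - cell.center[0]
    dc = cols - cell.center[1]
    ct, st = np.cos(cell.theta), np.sin(cell.theta)
    u = dr * ct + dc * st
    v = -dr * st + dc * ct
    return np.sqrt((u / cell.axes[0]) ** 2 + (v / cell.axes[1]) ** 2)


def _crop_window(shape, center, reach):
    r0 = max(int(center[0] - reach), 0)
    r1 = min(int(center[0] + reach) + 2, shape[0])
    c0 = max(int(center[1] - reach), 0)
    c1 = min(int(center[1] + reach) + 2, shape[1])
    return (slice(r0, r1), slice(c0, c1))


def _sample_arcs(rng: np.random.Generator, completeness: float
                 ) -> tuple[tuple[float, float], ...]:
    """Random kept angular intervals covering ``completeness`` of 2*pi."""
    if completeness >= 1.0:
        return ((0.0, 2 * np.pi),)
    missing = (1.0 - completeness) * 2 * np.pi
    start = rng.uniform(0, 2 * np.pi)
    # one deleted arc of the required total length, random phase
    lo, hi = start, start + missing
    kept = [(hi % (2 * np.pi), (lo + 2 * np.pi) if hi > 2 * np.pi else lo)]
    a, b = kept[0]
    if a < b:
        return ((a, b),)
    return ((0.0, b), (a, 2 * np.pi))


def _angle_in_arcs(angles: np.ndarray,
                   arcs: tuple[tuple[float, float], ...]) -> np.ndarray:
    keep = np.zeros(angles.shape, dtype=bool)
    for a, b in arcs:
        keep |= (angles >= a) & (angles <= b)
    return keep


def _place_cells(spec: FixtureSpec, rng: np.random.Generator) -> list[list[_Cell]]:
    """Sample cell groups (singletons, pairs, triples) without overlap."""
    H, W = spec.shape
    n = spec.n_cells
    n_pair_members = int(round(spec.touching_fraction * n / 2)) * 2
    n_triple_members = int(round(spec.triple_fraction * n / 3)) * 3
    n_singles = n - n_pair_members - n_triple_members
    if n_singles < 0:
        raise ValueError("touching/triple fractions exceed the cell budget")

    group_sizes = ([1] * n_singles + [2] * (n_pair_members // 2)
                   + [3] * (n_triple_members // 3))

    def sample_cell(center: np.ndarray) -> _Cell:
        a = rng.uniform(*spec.radius_range)
        ecc = rng.uniform(*spec.eccentricity_range)
        axes = np.array([a, a / ecc])
        return _Cell(
            center=center,
            axes=axes,
            theta=rng.uniform(0, np.pi),
            nucleus_peak=rng.uniform(*spec.nucleus_peak_range),
            membrane_peak=rng.uniform(*spec.membrane_peak_range),
        )

    margin = spec.radius_range[1] + spec.membrane_gap + spec.membrane_width + 2
    placed: list[list[_Cell]] = []
    occupied_centers: list[tuple[np.ndarray, float]] = []  # (center, clearance)

    def clearance(cell: _Cell) -> float:
        return float(cell.axes.max() + spec.membrane_gap + spec.membrane_width)

    def fits(cell: _Cell, ignore: list[_Cell]) -> bool:
        if not (margin <= cell.center[0] <= H - margin
                and margin <= cell.center[1] <= W - margin):
            return False
        for center, clr in occupied_centers:
            if any(center is o.center for o in ignore):
                continue
            if np.hypot(*(cell.center - center)) < clearance(cell) + clr + 2:
                return False
        return True

    max_tries = 500
    for size in group_sizes:
        for attempt in range(max_tries):
            c0 = rng.uniform([margin, margin], [H - margin, W - margin])
            group = [sample_cell(c0)]
            ok = fits(group[0], [])
            direction = rng.uniform(0, 2 * np.pi)
            while ok and len(group) < size:
                prev = group[-1]
                nxt = sample_cell(np.zeros(2))
                # abutting: centers closer than the sum of semi-axes so the
                # nucleus masks fuse into one component
                d = 0.82 * (prev.axes[0] + nxt.axes[0])
                step = direction + rng.uniform(-0.4, 0.4)
                nxt.center = prev.center + d * np.array([np.sin(step),
                                                         np.cos(step)])
                ok = fits(nxt, group)
                group.append(nxt)
            if ok:
                placed.append(group)
                for cell in group:
                    occupied_centers.append((cell.center, clearance(cell)))
                break
        else:
            raise RuntimeError(
                f"placement failed after {max_tries} tries for a group of "
                f"{size} cells: density too high for shape {spec.shape}"
            )
    return placed


def generate_tissue(spec: FixtureSpec) -> FixtureBundle:
    """Render one tissue field with exact ground truth.

    Nuclei and cells are drawn as (possibly abutting) ellipses; overlapping
    claims are resolved by proximity to the nearest nucleus so touching
    groups share walls. Identical specs (including seed) yield identical
    bundles.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.shape
    groups = _place_cells(spec, rng)
    cells = [c for g in groups for c in g]

    # statuses: membrane-free and nucleus-free assignments (exact counts);
    # only singleton cells are eligible so group geometry stays coherent
    n_mem_free = int(round(spec.membrane_free_fraction * spec.n_cells))
    n_nuc_free = int(round(spec.nucleus_free_fraction * spec.n_cells))
    singleton_idx = [i for i, g in enumerate(groups) if len(g) == 1]
    pick = rng.permutation(singleton_idx)
    if n_mem_free + n_nuc_free > len(singleton_idx):
        raise RuntimeError("not enough singleton cells for the requested "
                           "membrane-free / nucleus-free fractions")
    for i in pick[:n_mem_free]:
        groups[i][0].has_membrane = False
    for i in pick[n_mem_free:n_mem_free + n_nuc_free]:
        groups[i][0].has_nucleus = False

    for cell in cells:
        cell.arc_kept = _sample_arcs(rng, spec.membrane_completeness)

    nucleus_chan = np.zeros((H, W))
    membrane_chan = np.zeros((H, W))
    # claims for ground truth: nucleus and cell elliptical distance per cell
    gt_nuclei = np.zeros((H, W), dtype=np.int64)
    gt_cells = np.zeros((H, W), dtype=np.int64)
    best_nuc = np.full((H, W), np.inf)
    best_cell = np.full((H, W), np.inf)

    nucleus_id = 0
    membrane_free_ids: list[int] = []
    nucleus_free_cell_ids: list[int] = []
    nucleus_cell_of: dict[int, int] = {}
    cell_ids: list[int] = []
    for cell in cells:
        cid = len(cell_ids) + 1
        cell_ids.append(cid)
        reach = cell.outer_axes(spec.membrane_gap, spec.membrane_width).max() + 2
        win = _crop_window((H, W), cell.center, reach)
        sub_shape = (win[0].stop - win[0].start, win[1].stop - win[1].start)
        offset_cell = _Cell(
            center=cell.center - np.array([win[0].start, win[1].start]),
            axes=cell.axes, theta=cell.theta,
            nucleus_peak=cell.nucleus_peak, membrane_peak=cell.membrane_peak,
        )
        rho = _elliptical_radius(sub_shape, offset_cell)
        outer = cell.outer_axes(spec.membrane_gap, spec.membrane_width)
        rho_outer = _elliptical_radius(sub_shape, _Cell(
            center=offset_cell.center, axes=outer, theta=cell.theta,
            nucleus_peak=0, membrane_peak=0))
        inner_ring = outer - spec.membrane_width
        rho_ring_inner = _elliptical_radius(sub_shape, _Cell(
            center=offset_cell.center, axes=inner_ring, theta=cell.theta,
            nucleus_peak=0, membrane_peak=0))

        cell_mask = rho_outer <= 1.0
        closer = rho_outer < best_cell[win]
        claim_cell = cell_mask & closer
        gt_cells[win][claim_cell] = cid
        best_cell[win][claim_cell] = rho_outer[claim_cell]

        if cell.has_nucleus:
            nucleus_id += 1
            nucleus_cell_of[nucleus_id] = cid
            nuc_mask = rho <= 1.0
            closer_n = rho < best_nuc[win]
            claim_nuc = nuc_mask & closer_n
            gt_nuclei[win][claim_nuc] = nucleus_id
            best_nuc[win][claim_nuc] = rho[claim_nuc]
            jitter = 1.0 + rng.normal(0.0, spec.intensity_jitter)
            profile = cell.nucleus_peak * jitter * (
                1.0 - spec.falloff * np.clip(rho, 0, 1) ** 2)
            nucleus_chan[win][nuc_mask] = np.maximum(
                nucleus_chan[win][nuc_mask], profile[nuc_mask])
        else:
            nucleus_free_cell_ids.append(cid)

        if cell.has_membrane:
            ring = (rho_ring_inner >= 1.0) & (rho_outer <= 1.0)
            rows, colsg = np.mgrid[0:sub_shape[0], 0:sub_shape[1]]
            ang = np.mod(np.arctan2(rows - offset_cell.center[0],
                                    colsg - offset_cell.center[1]), 2 * np.pi)
            ring &= _angle_in_arcs(ang, cell.arc_kept)
            jitter = 1.0 + rng.normal(0.0, spec.intensity_jitter)
            membrane_chan[win][ring] = np.maximum(
                membrane_chan[win][ring], cell.membrane_peak * jitter)
        else:
            membrane_free_ids.append(cid)

    # shared walls: abutting-group cells already draw rings; where two cells'
    # ground truths touch, membrane is present from both sides by construction

    # enforce nucleus-within-cell exactly: pixels claimed by a nucleus belong
    # to that nucleus's cell even where the outer-ellipse competition differed
    if nucleus_id:
        lut = np.zeros(nucleus_id + 1, dtype=np.int64)
        for nid, cid in nucleus_cell_of.items():
            lut[nid] = cid
        nuc_pixels = gt_nuclei > 0
        gt_cells[nuc_pixels] = lut[gt_nuclei[nuc_pixels]]

    # optics: finite-resolution blur softens edges the way the microscope
    # point-spread function does, so marker intensity ramps down gradually
    # instead of stepping to zero at object boundaries
    if spec.blur_sigma > 0:
        nucleus_chan = ndi.gaussian_filter(nucleus_chan, spec.blur_sigma)
        membrane_chan = ndi.gaussian_filter(membrane_chan, spec.blur_sigma)

    noise = rng.normal(0.0, spec.noise_std, size=(H, W))
    nucleus_chan = np.clip(nucleus_chan + noise, 0.0, 1.0)
    noise2 = rng.normal(0.0, spec.noise_std, size=(H, W))
    membrane_chan = np.clip(membrane_chan + noise2, 0.0, 1.0)

    image = TwoChannelImage(nucleus=nucleus_chan, membrane=membrane_chan)
    return FixtureBundle(
        image=image,
        gt_nuclei=gt_nuclei,
        gt_cells=gt_cells,
        spec=spec,
        membrane_free_ids=membrane_free_ids,
        nucleus_free_cell_ids=nucleus_free_cell_ids,
    )


def generate_cluster(
    k: int,
    radii: float | tuple[float, ...] = 10.0,
    center_distance_factor: float = 1.6,
    seed: int = 0,
    membrane_wall: bool = False,
    noise_std: float = 0.0,
    pad: int = 8,
) -> FixtureBundle:
    """A single cluster of ``k`` fused disk nuclei with known ground truth.

    Centers are laid on a horizontal chain, consecutive centers separated by
    ``center_distance_factor`` times the larger radius, so the nucleus masks
    fuse into one component for factors below 2. ``membrane_wall`` draws a
    1-px membrane line between consecutive nuclei.
    """
    if k not in (2, 3):
        raise ValueError("k must be 2 or 3")
    rng = np.random.default_rng(seed)
    rr = np.broadcast_to(np.asarray(radii, dtype=float), (k,)).copy()
    d = [center_distance_factor * max(rr[i], rr[i + 1]) for i in range(k - 1)]
    H = int(2 * rr.max() + 2 * pad)
    W = int(sum(d) + rr[0] + rr[-1] + 2 * pad)
    centers = []
    x = pad + rr[0]
    for i in range(k):
        centers.append(np.array([H / 2.0, x]))
        if i < k - 1:
            x += d[i]
    rows, cols = np.mgrid[0:H, 0:W]
    gt = np.zeros((H, W), dtype=np.int64)
    best = np.full((H, W), np.inf)
    chan = np.zeros((H, W))
    for i, (c, r) in enumerate(zip(centers, rr), start=1):
        dist = np.hypot(rows - c[0], cols - c[1]) / r
        mask = dist <= 1.0
        claim = mask & (dist < best)
        gt[claim] = i
        best[claim] = dist[claim]
        chan[mask] = np.maximum(chan[mask], 0.85 * (1 - 0.5 * dist[mask] ** 2))
    membrane = np.zeros((H, W))
    if membrane_wall:
        for i in range(k - 1):
            mid = (centers[i][1] + centers[i + 1][1]) / 2.0
            col = int(round(mid))
            wall = (np.abs(cols - col) <= 0) & (gt > 0)
            membrane[wall] = 0.8
    if noise_std > 0:
        chan = np.clip(chan + rng.normal(0, noise_std, chan.shape), 0, 1)
        membrane = np.clip(membrane + rng.normal(0, noise_std, chan.shape), 0, 1)
    spec = FixtureSpec(shape=(H, W), n_cells=k, noise_std=noise_std, seed=seed)
    image = TwoChannelImage(nucleus=chan, membrane=membrane)
    return FixtureBundle(image=image, gt_nuclei=gt, gt_cells=gt.copy(), spec=spec)
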