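"""Stage 3: parse the nucleus semantic mask into individual nuclei.

Connected components of the posterior global nucleus mask are classified by
convexity analysis (area filter, steepest-concave-point depth); non-convex
components — nucleus clusters — are split by a perturbed watershed whose
seeds come from thresholding the distance transform at its mean nonzero
value and are validated by shifting all of them simultaneously by
``±⌊d_avr⌋``: seeds whose region collapses to a point object (or leaves the
mask) under any shift are spurious and removed. Clusters the perturbed
watershed cannot split fall through to virtual cuts: a cut through the
steepest concave point supplies two seed points for an ordinary watershed
on the uncut mask. Splitting recurses until sub-regions are convex.

``perturbed_watershed`` and ``virtual_cuts`` are modality-agnostic and
callable on any binary mask (plus an optional cut mask).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import label as cc_label
from skimage.morphology import closing, disk, opening
from skimage.segmentation import watershed

from .core_io import UnsegParams, relabel_raster_order

logger = logging.getLogger("unseg")

__all__ = [
    "ComponentRecord",
    "steepest_concave_point",
    "convexity_analysis",
    "perturbed_watershed",
    "virtual_cuts",
    "split_cluster",
    "segment_nuclei",
]


@dataclass
class ComponentRecord:
    """One connected component of the nucleus mask and its classification."""

    component_id: int
    area: int
    scp_location: tuple[int, int]
    scp_depth: float
    classification: str = "nucleus"  # discarded | nucleus | NC | SC


# ---------------------------------------------------------------------------
# convexity analysis
# ---------------------------------------------------------------------------

def _boundary_pixels(mask: np.ndarray) -> np.ndarray:
    eroded = ndi.binary_erosion(mask, structure=np.ones((3, 3)), border_value=0)
    return np.argwhere(mask & ~eroded)


def _scp_with_chord(mask: np.ndarray):
    """SCP location, depth and the hull edge (chord) spanning the concavity."""
    mask = np.asarray(mask, dtype=bool)
    pts = np.argwhere(mask)
    if pts.shape[0] < 3:
        loc = tuple(pts[0]) if pts.shape[0] else (0, 0)
        return loc, 0.0, None
    try:
        hull = ConvexHull(pts.astype(float))
    except QhullError:  # collinear pixel sets are convex
        return tuple(pts[0]), 0.0, None
    verts = pts[hull.vertices].astype(float)
    a = verts
    b = np.roll(verts, -1, axis=0)
    ab = b - a                                     # (E, 2)
    bpix = _boundary_pixels(mask).astype(float)    # (B, 2)
    # point-to-segment distances, vectorized over boundary x edges
    ap = bpix[:, None, :] - a[None, :, :]          # (B, E, 2)
    denom = np.einsum("ej,ej->e", ab, ab)
    denom = np.where(denom > 0, denom, 1.0)
    t = np.clip(np.einsum("bej,ej->be", ap, ab) / denom, 0.0, 1.0)
    proj = a[None, :, :] + t[..., None] * ab[None, :, :]
    dist = np.linalg.norm(bpix[:, None, :] - proj, axis=2)  # (B, E)
    nearest_edge = np.argmin(dist, axis=1)
    d_hull = dist[np.arange(dist.shape[0]), nearest_edge]
    order = np.lexsort((bpix[:, 1], bpix[:, 0], -d_hull))
    best = order[0]
    loc = (int(bpix[best, 0]), int(bpix[best, 1]))
    e = nearest_edge[best]
    return loc, float(d_hull[best]), (a[e], b[e])


def steepest_concave_point(mask: np.ndarray) -> tuple[tuple[int, int], float]:
    """Boundary point of maximal deviation from the component's convex hull.

    Returns ``(location, depth)``. Depth is the Euclidean distance from the
    point to the convex-hull polygon; convex shapes score near 0 (up to
    ~1 px of digitization, since the boundary chain of an ideal disk sags
    below hull edges between lattice vertices). Components with fewer than
    3 pixels get depth 0.
    """
    loc, depth, _ = _scp_with_chord(mask)
    return loc, depth


def convexity_analysis(
    labels: np.ndarray, a0: int, d0: float
) -> list[ComponentRecord]:
    """Classify each labeled component as discarded / NC / nucleus candidate.

    Components with area ``<= a0`` are discarded; remaining components with
    concavity depth ``> d0`` are nucleus clusters (NC); the rest are nucleus
    candidates. Small-component (SC) tagging happens later, once the
    candidate area distribution is known.
    """
    records: list[ComponentRecord] = []
    for sl, cid in zip(ndi.find_objects(labels), range(1, int(labels.max()) + 1)):
        if sl is None:
            continue
        mask = labels[sl] == cid
        area = int(mask.sum())
        if area <= a0:
            records.append(ComponentRecord(cid, area, (0, 0), 0.0, "discarded"))
            continue
        (r, c), depth = steepest_concave_point(mask)
        loc = (r + sl[0].start, c + sl[1].start)
        cls = "NC" if depth > d0 else "nucleus"
        records.append(ComponentRecord(cid, area, loc, depth, cls))
    return records


# ---------------------------------------------------------------------------
# perturbed watershed
# ---------------------------------------------------------------------------

def _seed_points(dt: np.ndarray, regions: np.ndarray, n: int) -> list[tuple[int, int]]:
    """Per sub-region DT argmax; ties broken to the smallest (row, col)."""
    seeds = []
    for lbl in range(1, n + 1):
        sel = regions == lbl
        vals = np.where(sel, dt, -np.inf)
        flat = np.argmax(vals)  # np.argmax returns the first (raster) maximum
        seeds.append(tuple(int(v) for v in np.unravel_index(flat, dt.shape)))
    return seeds


def _run_watershed(neg_dt: np.ndarray, mask: np.ndarray,
                   seeds: list[tuple[int, int] | None]) -> np.ndarray:
    markers = np.zeros(mask.shape, dtype=np.int32)
    for j, s in enumerate(seeds, start=1):
        if s is not None:
            markers[s] = j
    return watershed(neg_dt, markers, mask=mask, connectivity=2)


def perturbed_watershed(
    nc_mask: np.ndarray,
    membrane_cut: np.ndarray | None = None,
    params: UnsegParams | None = None,
) -> list[np.ndarray]:
    """Split a nucleus-cluster mask by perturbation-validated watershed.

    Steps: cut the mask where the (optional) membrane mask indicates
    membrane; take the Euclidean distance transform (DT) of the cut mask;
    threshold it at ``d_avr`` (the mean of its nonzero values) to find
    sub-regions, seeding each at its DT argmax; run a marker watershed, then
    re-run it four times with all seeds shifted simultaneously by
    ``±⌊d_avr⌋`` along rows and columns. A seed is unstable if in any run
    its region's area drops to ``collapse_area`` or below, or the shifted
    seed leaves the mask. The final watershed keeps only stable seeds;
    pixels removed by the membrane cut are reassigned to the nearest
    sub-region so the output partitions the input mask.

    Returns a list of boolean sub-masks (length >= 1). The number of output
    regions never exceeds the number of initial watershed regions.
    """
    params = params or UnsegParams()
    nc_mask = np.asarray(nc_mask, dtype=bool)
    modified = nc_mask.copy()
    if membrane_cut is not None:
        modified &= ~np.asarray(membrane_cut, dtype=bool)
    if not modified.any():
        logger.warning("perturbed_watershed: mask empty after membrane cuts; "
                       "returning the uncut component")
        return [nc_mask.copy()]

    dt = ndi.distance_transform_edt(modified)
    d_avr = float(dt[dt > 0].mean())
    shift = int(np.floor(d_avr))
    regions, n = cc_label(dt >= d_avr, connectivity=2, return_num=True)
    seeds = _seed_points(dt, regions, n)
    neg_dt = -dt

    if n > 1 and shift >= 1:
        unstable: set[int] = set()
        H, W = modified.shape
        for dr, dc in ((0, shift), (0, -shift), (shift, 0), (-shift, 0)):
            shifted: list[tuple[int, int] | None] = []
            for j, (r, c) in enumerate(seeds):
                q = (r + dr, c + dc)
                if not (0 <= q[0] < H and 0 <= q[1] < W) or not modified[q]:
                    unstable.add(j)
                    shifted.append(None)
                else:
                    shifted.append(q)
            ws = _run_watershed(neg_dt, modified, shifted)
            areas = np.bincount(ws.ravel(), minlength=len(seeds) + 1)
            for j, s in enumerate(shifted):
                if s is not None and areas[j + 1] <= params.collapse_area:
                    unstable.add(j)
        survivors = [s for j, s in enumerate(seeds) if j not in unstable]
        if not survivors:
            # every seed failed perturbation: keep the deepest-DT one so the
            # component is still returned
            survivors = [seeds[int(np.argmax([dt[s] for s in seeds]))]]
        final = _run_watershed(neg_dt, modified, survivors)
        n_final = len(survivors)
    else:
        final = np.where(modified, 1, 0).astype(np.int32)
        n_final = 1

    # reassign cut pixels to the nearest labeled sub-region
    leftover = nc_mask & (final == 0)
    if leftover.any():
        _, (ir, ic) = ndi.distance_transform_edt(final == 0, return_indices=True)
        final = final.copy()
        final[leftover] = final[ir[leftover], ic[leftover]]

    return [final == j for j in range(1, n_final + 1) if (final == j).any()]


# ---------------------------------------------------------------------------
# virtual cuts
# ---------------------------------------------------------------------------

def _cut_line(shape: tuple[int, int], point: np.ndarray,
              direction: np.ndarray) -> np.ndarray:
    cut = np.zeros(shape, dtype=bool)
    H, W = shape
    reach = float(H + W)
    for s in np.arange(-reach, reach, 0.5):
        q = np.round(point + s * direction).astype(int)
        if 0 <= q[0] < H and 0 <= q[1] < W:
            cut[q[0], q[1]] = True
    return cut


def virtual_cuts(
    nc_mask: np.ndarray, convex_tol: float = 1.0
) -> tuple[tuple[int, int], tuple[int, int]] | None:
    """Two watershed seed points derived from a cut through the SCP.

    A 1-pixel line through the steepest concave point, perpendicular to the
    convex-hull chord spanning the concavity, divides the mask into virtual
    sub-regions; the two largest contribute one seed each at their internal
    distance-transform argmax. The cut itself is never applied to the mask —
    the caller runs the actual watershed on the *uncut* mask with these
    seeds. Returns ``None`` when the cut fails to split the mask
    (degenerate geometry).

    Raises ``ValueError`` on convex input (depth within the 1-px
    discretization tolerance — the boundary chain of an ideal digital disk
    deviates up to ~1 px from its convex hull): such components should
    never reach the virtual-cut path.
    """
    nc_mask = np.asarray(nc_mask, dtype=bool)
    loc, depth, chord = _scp_with_chord(nc_mask)
    if depth <= convex_tol or chord is None:
        raise ValueError(
            f"virtual_cuts requires a non-convex component "
            f"(depth {depth:.2f} <= {convex_tol:.2f})"
        )
    a, b = chord
    ab = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    ab /= np.hypot(*ab)
    normal = np.array([-ab[1], ab[0]])  # perpendicular to the chord
    cut = _cut_line(nc_mask.shape, np.asarray(loc, dtype=float), normal)
    halves = cc_label(nc_mask & ~cut, connectivity=1)
    sizes = np.bincount(halves.ravel())
    sizes[0] = 0
    if (sizes > 0).sum() < 2:
        logger.info("virtual_cuts: cut failed to split the component")
        return None
    top2 = np.argsort(sizes)[::-1][:2]
    dt = ndi.distance_transform_edt(nc_mask)
    seeds = []
    for lbl in sizes.argsort()[::-1][:2]:
        vals = np.where(halves == lbl, dt, -np.inf)
        flat = int(np.argmax(vals))
        seeds.append(tuple(int(v) for v in np.unravel_index(flat, dt.shape)))
    return seeds[0], seeds[1]


def _vc_split(nc_mask: np.ndarray) -> list[np.ndarray] | None:
    """Watershed of the uncut mask seeded by the virtual-cut seed pair."""
    seeds = virtual_cuts(nc_mask)
    if seeds is None:
        return None
    dt = ndi.distance_transform_edt(nc_mask)
    ws = _run_watershed(-dt, nc_mask, list(seeds))
    parts = [ws == j for j in (1, 2) if (ws == j).any()]
    return parts if len(parts) == 2 else None


def split_cluster(
    nc_mask: np.ndarray,
    membrane_cut: np.ndarray | None = None,
    params: UnsegParams | None = None,
) -> list[np.ndarray]:
    """Split one nucleus cluster: perturbed watershed, then virtual cuts.

    The perturbed watershed handles clusters whose distance transform
    exposes multiple interior maxima; when it returns a single region the
    virtual-cut fallback supplies two seeds through the steepest concave
    point. Returns >= 1 sub-masks partitioning the cluster.
    """
    params = params or UnsegParams()
    subs = perturbed_watershed(nc_mask, membrane_cut, params)
    if len(subs) > 1:
        return subs
    try:
        vc = _vc_split(nc_mask)
    except ValueError:
        vc = None
    return vc if vc is not None else subs


# ---------------------------------------------------------------------------
# full stage-3 orchestration
# ---------------------------------------------------------------------------

def _smooth_instances(labels: np.ndarray, radius: int) -> np.ndarray:
    """Per-instance closing-then-opening; contested pixels resolved by
    proximity to the original instances; each id keeps its largest
    8-connected piece."""
    if radius < 1 or labels.max() == 0:
        return labels
    selem = disk(radius)
    pad = radius + 1
    out = np.zeros_like(labels)
    claims = np.zeros(labels.shape, dtype=np.int16)
    for sl, lbl in zip(ndi.find_objects(labels), range(1, int(labels.max()) + 1)):
        if sl is None:
            continue
        rsl = tuple(
            slice(max(s.start - pad, 0), min(s.stop + pad, dim))
            for s, dim in zip(sl, labels.shape)
        )
        mask = labels[rsl] == lbl
        sm = opening(closing(mask, selem), selem)
        if not sm.any():
            sm = mask  # smoothing annihilated the object: keep the original
        # keep the largest connected piece
        cc = cc_label(sm, connectivity=2)
        if cc.max() > 1:
            sizes = np.bincount(cc.ravel())
            sizes[0] = 0
            sm = cc == int(np.argmax(sizes))
        region = out[rsl]
        region[sm] = lbl
        claims[rsl][sm] += 1
    contested = claims > 1
    if contested.any():
        # proximity competition against the original (disjoint) label map
        _, (ir, ic) = ndi.distance_transform_edt(labels == 0, return_indices=True)
        out[contested] = labels[ir[contested], ic[contested]]
    return out


def segment_nuclei(
    Mg: np.ndarray, Ml: np.ndarray, params: UnsegParams | None = None
) -> np.ndarray:
    """Stage-3 orchestration: semantic masks -> nucleus instance labels.

    Components of the posterior global nucleus class are classified by
    convexity analysis; clusters are split recursively (perturbed watershed
    with virtual-cut fallback, each sub-region re-entering the analysis,
    bounded by ``max_recursion`` and by strict area decrease). Nucleus
    candidates far below the typical candidate area are kept only when
    isolated. Instance boundaries are smoothed by closing/opening with a
    disk of ``smoothing_radius``.
    """
    params = params or UnsegParams()
    Mg = np.asarray(Mg)
    Ml = np.asarray(Ml)
    nuc_mask = Mg == 1
    mem_local = Ml == 2
    H, W = nuc_mask.shape
    if not nuc_mask.any():
        return np.zeros((H, W), dtype=np.int64)

    comp_labels, n_comp = cc_label(nuc_mask, connectivity=2, return_num=True)
    slices = ndi.find_objects(comp_labels)

    accepted: list[tuple[np.ndarray, tuple[slice, slice]]] = []
    # queue entries: (bool mask crop, global slice, recursion depth)
    queue: list[tuple[np.ndarray, tuple[slice, slice], int]] = []
    for cid, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        queue.append((comp_labels[sl] == cid, sl, 0))

    while queue:
        mask, sl, depth = queue.pop()
        area = int(mask.sum())
        if area <= params.a0:
            continue
        _, scp_depth = steepest_concave_point(mask)
        if scp_depth <= params.d0:
            accepted.append((mask, sl))
            continue
        if depth >= params.max_recursion:
            logger.info("segment_nuclei: recursion cap hit; accepting component")
            accepted.append((mask, sl))
            continue
        subs = split_cluster(mask, mem_local[sl], params)
        if len(subs) <= 1 or any(int(s.sum()) >= area for s in subs):
            accepted.append((mask, sl))
            continue
        for s in subs:
            queue.append((s, sl, depth + 1))

    if not accepted:
        return np.zeros((H, W), dtype=np.int64)

    # small-component isolation filter
    areas = np.array([int(m.sum()) for m, _ in accepted], dtype=float)
    median_area = float(np.median(areas))
    sc_cut = params.sc_area_factor * median_area
    labels = np.zeros((H, W), dtype=np.int64)
    for i, (mask, sl) in enumerate(accepted, start=1):
        labels[sl][mask] = i
    keep = np.ones(len(accepted) + 1, dtype=bool)
    struct = disk(params.sc_isolation_px)
    for i, (mask, sl) in enumerate(accepted, start=1):
        if areas[i - 1] >= sc_cut:
            continue
        pad = params.sc_isolation_px + 1
        rsl = tuple(
            slice(max(s.start - pad, 0), min(s.stop + pad, dim))
            for s, dim in zip(sl, (H, W))
        )
        local = labels[rsl]
        grown = ndi.binary_dilation(local == i, structure=struct)
        if np.any((local > 0) & (local != i) & grown):
            keep[i] = False  # non-isolated small component: dropped
    labels[~keep[labels]] = 0

    labels = _smooth_instances(labels, params.smoothing_radius)
    return relabel_raster_order(labels)
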