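"""Brute-force reference implementations used as test oracles.

Every function here trades speed for obviousness: plain loops and exhaustive
searches that can be checked by eye, against which the package's vectorized
implementations are compared.
"""

from itertools import combinations, permutations

import numpy as np


def lmsf_oracle(I, t0, n0):
    """Double-loop local mean suppression filter (zero padding, full divisor)."""
    I = np.asarray(I, dtype=float)
    H, W = I.shape
    size = 2 * n0 + 1
    out = np.zeros_like(I)
    for r in range(H):
        for c in range(W):
            total = 0.0
            for dr in range(-n0, n0 + 1):
                for dc in range(-n0, n0 + 1):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < H and 0 <= cc < W:
                        total += I[rr, cc]
            mean = total / (size * size)
            if mean > 0 and I[r, c] / mean >= t0:
                out[r, c] = I[r, c]
    return out


def gas_oracle(I, k0):
    """Per-pixel gradient-adaptive smoothing (replicated borders)."""
    I = np.asarray(I, dtype=float)
    H, W = I.shape

    def at(r, c):
        return I[min(max(r, 0), H - 1), min(max(c, 0), W - 1)]

    w = np.zeros_like(I)
    for r in range(H):
        for c in range(W):
            gr = (at(r + 1, c) - at(r - 1, c)) / 2.0
            gc = (at(r, c + 1) - at(r, c - 1)) / 2.0
            w[r, c] = np.exp(-(gr * gr + gc * gc) / (2.0 * k0 * k0))

    def wat(r, c):
        return w[min(max(r, 0), H - 1), min(max(c, 0), W - 1)]

    out = np.zeros_like(I)
    for r in range(H):
        for c in range(W):
            num = den = 0.0
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    num += at(r + dr, c + dc) * wat(r + dr, c + dc)
                    den += wat(r + dr, c + dc)
            out[r, c] = num / den
    return out


def multiotsu3_oracle(data, nbins=256):
    """Exhaustive 3-class Otsu threshold pair over an nbins histogram."""
    hist, edges = np.histogram(np.asarray(data).ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    p = hist / hist.sum()
    best, arg = -1.0, None
    for i, j in combinations(range(nbins - 1), 2):
        crit = 0.0
        for lo, hi in ((0, i + 1), (i + 1, j + 1), (j + 1, nbins)):
            w = p[lo:hi].sum()
            if w > 0:
                mu = (p[lo:hi] * centers[lo:hi]).sum() / w
                crit += w * mu * mu
        if crit > best:
            best, arg = crit, (i, j)
    return centers[arg[0]], centers[arg[1]]


def _otsu_u8(vals):
    """2-class Otsu threshold of a uint8 sample (first-maximum convention)."""
    vals = np.asarray(vals, dtype=float)
    best, arg = -1.0, 0
    for t in range(256):
        lo = vals[vals <= t]
        hi = vals[vals > t]
        if lo.size == 0 or hi.size == 0:
            crit = 0.0
        else:
            crit = lo.size * hi.size * (lo.mean() - hi.mean()) ** 2
        if crit > best:
            best, arg = crit, t
    return arg


def local_otsu_oracle(u8, footprint):
    """Sliding-window 2-class Otsu threshold grid for a uint8 image."""
    u8 = np.asarray(u8)
    H, W = u8.shape
    rad = footprint.shape[0] // 2
    offs = np.argwhere(footprint) - rad
    out = np.zeros_like(u8)
    for r in range(H):
        for c in range(W):
            pts = offs + (r, c)
            ok = ((pts[:, 0] >= 0) & (pts[:, 0] < H)
                  & (pts[:, 1] >= 0) & (pts[:, 1] < W))
            out[r, c] = _otsu_u8(u8[pts[ok, 0], pts[ok, 1]])
    return out


def point_to_hull_depth_oracle(mask):
    """Max boundary-pixel distance to the convex-hull polygon (plain loops)."""
    from scipy import ndimage as ndi
    from scipy.spatial import ConvexHull

    mask = np.asarray(mask, dtype=bool)
    pts = np.argwhere(mask).astype(float)
    hull = ConvexHull(pts)
    verts = pts[hull.vertices]
    edges = [(verts[i], verts[(i + 1) % len(verts)]) for i in range(len(verts))]
    eroded = ndi.binary_erosion(mask, structure=np.ones((3, 3)), border_value=0)
    boundary = np.argwhere(mask & ~eroded).astype(float)

    def seg_dist(p, a, b):
        ab = b - a
        denom = float(ab @ ab)
        t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0, 1))
        return float(np.linalg.norm(p - (a + t * ab)))

    best = 0.0
    for p in boundary:
        d = min(seg_dist(p, a, b) for a, b in edges)
        best = max(best, d)
    return best


def optimal_matching_oracle(pred, gt, threshold):
    """Exhaustive one-to-one assignment maximizing the number of matches.

    Only feasible for a handful of objects; returns (tp, fp, fn).
    """
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    gt_ids = [int(i) for i in np.unique(gt) if i > 0]
    pred_ids = [int(i) for i in np.unique(pred) if i > 0]
    iou = {}
    for g in gt_ids:
        gm = gt == g
        for p in pred_ids:
            pm = pred == p
            inter = int((gm & pm).sum())
            if inter:
                iou[(g, p)] = inter / int((gm | pm).sum())
    best = 0
    k = min(len(gt_ids), len(pred_ids))
    for gsub in combinations(gt_ids, k):
        for psub in permutations(pred_ids, k):
            tp = sum(
                1 for g, p in zip(gsub, psub)
                if iou.get((g, p), 0.0) > threshold
            )
            best = max(best, tp)
    return best, len(pred_ids) - best, len(gt_ids) - best


def median_curve_oracle(stack):
    """Sort-based pointwise median over a (curves, thresholds) array."""
    stack = np.asarray(stack, dtype=float)
    out = np.zeros(stack.shape[1])
    for j in range(stack.shape[1]):
        col = sorted(stack[:, j])
        n = len(col)
        mid = n // 2
        out[j] = col[mid] if n % 2 else (col[mid - 1] + col[mid]) / 2.0
    return out
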