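"""Domain types, image loading/normalization, and label-map output.

Conventions used throughout the package:

* all grids are 2D numpy arrays indexed ``(row, col)``, 0-based, origin at
  the top-left corner;
* intensity channels are ``float64`` in ``[0, 1]``;
* binary masks are boolean arrays;
* semantic label maps are small-integer arrays over ``{0, 1, 2}``
  (background / nucleus / cell membrane);
* instance label maps are non-negative integer arrays, ``0`` = background,
  positive ids = objects (ids need not be contiguous internally, but written
  outputs are relabeled ``1..N`` in raster order of each object's first
  pixel).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi

logger = logging.getLogger("unseg")

__all__ = [
    "TwoChannelImage",
    "UnsegParams",
    "normalize_channel",
    "load_two_channel_image",
    "write_outputs",
    "relabel_raster_order",
    "validate_probability_field",
    "validate_semantic_labels",
]


@dataclass(frozen=True)
class TwoChannelImage:
    """A paired, normalized nucleus/membrane intensity image.

    Attributes
    ----------
    nucleus, membrane:
        Per-channel intensity grids over a shared pixel domain, each
        independently scaled to ``[0, 1]``.
    pixel_pitch:
        Optional micrometers-per-pixel metadata; unused by the algorithm.
    """

    nucleus: np.ndarray
    membrane: np.ndarray
    pixel_pitch: float | None = None

    def __post_init__(self) -> None:
        nuc = np.asarray(self.nucleus, dtype=float)
        mem = np.asarray(self.membrane, dtype=float)
        if nuc.ndim != 2 or mem.ndim != 2:
            raise ValueError("channels must be 2D grids")
        if nuc.shape != mem.shape:
            raise ValueError(
                f"channel shapes differ: {nuc.shape} vs {mem.shape}"
            )
        for name, arr in (("nucleus", nuc), ("membrane", mem)):
            if not np.isfinite(arr).all():
                raise ValueError(f"{name} channel contains non-finite values")
            if arr.min() < 0 or arr.max() > 1:
                raise ValueError(f"{name} channel not normalized to [0, 1]")
        object.__setattr__(self, "nucleus", nuc)
        object.__setattr__(self, "membrane", mem)

    @property
    def shape(self) -> tuple[int, int]:
        return self.nucleus.shape


@dataclass
class UnsegParams:
    """All tunable constants of the segmentation pipeline.

    Parameters
    ----------
    sigma:
        Standard deviation (pixels) of the Gaussian pre-filter used for the
        initial foreground estimate. Default 3.
    t0:
        Local-mean-suppression ratio threshold in (0, 1). A pixel is zeroed
        when its intensity falls below ``t0`` times its local window mean.
        Default 0.5.
    n0_list:
        Half-widths of the LMSF windows; each scale detects inter-cell
        valleys of a different width. Default (5, 10, 20, 40).
    p1, p2:
        Prior-probability refinement thresholds for the nucleus and membrane
        global masks. Default 0.01 each.
    k0:
        Gradient-adaptive-smoothing scale. Default 1.
    r0:
        Disk radius (pixels) of the local Otsu neighborhood. Default 5.
    a0:
        Minimal component area (pixels) kept during convexity analysis.
        Default 20.
    d0:
        Concavity-depth threshold (pixels) above which a component is a
        nucleus cluster to be split. Default 4.
    u0:
        Fallback dilation (pixels) used for cells without membrane evidence.
        Default 9, valid range 1-10.
    labeling_mode:
        ``"argmax"`` (default) or ``"kmeans"`` semantic labeling.
    collapse_area:
        Area (pixels) at or below which a watershed region counts as
        collapsed to a point object during seed perturbation. Default 4.
    smoothing_radius:
        Disk radius of the per-instance boundary smoothing. Default 1.
    max_recursion:
        Cap on the cluster-splitting recursion depth. Default 10.
    rng_seed:
        Seed for the k-means labeling mode.
    sc_area_factor:
        Nucleus candidates smaller than this fraction of the median accepted
        candidate area form the small-component (SC) list. Default 0.5.
    sc_isolation_px:
        An SC is "isolated" (and kept) when its dilation by this many pixels
        touches no other accepted nucleus. Default 2.
    membrane_support_frac:
        Minimum fraction of membrane pixels in the nucleus-to-u0 ring for a
        nucleus to be expanded by watershed rather than plain dilation.
        Default 0.2.
    nucleus_free_overlap_tol:
        Maximum fractional overlap of a candidate nucleus-free cell with
        existing cells. Default 0.1.
    nucleus_free_min_solidity:
        Minimum solidity (area over convex-hull area) for a candidate
        nucleus-free cell. Cells are approximately convex; the strongly
        concave interstitial pockets enclosed between the membranes of
        abutting cells are rejected by this test. Default 0.7.
    default_mean_nucleus_area:
        Mean nucleus area (pixels) assumed when no nuclei were segmented.
    """

    sigma: float = 3.0
    t0: float = 0.5
    n0_list: tuple[int, ...] = (5, 10, 20, 40)
    p1: float = 0.01
    p2: float = 0.01
    k0: float = 1.0
    r0: int = 5
    a0: int = 20
    d0: float = 4.0
    u0: int = 9
    labeling_mode: str = "argmax"
    collapse_area: int = 4
    smoothing_radius: int = 1
    max_recursion: int = 10
    rng_seed: int = 0
    sc_area_factor: float = 0.5
    sc_isolation_px: int = 2
    membrane_support_frac: float = 0.2
    nucleus_free_overlap_tol: float = 0.1
    nucleus_free_min_solidity: float = 0.7
    default_mean_nucleus_area: float = 300.0

    def __post_init__(self) -> None:
        self.n0_list = tuple(int(n) for n in self.n0_list)
        self.validate()

    def validate(self) -> None:
        if not 0 < self.t0 < 1:
            raise ValueError("t0 must lie in (0, 1)")
        for name in ("p1", "p2"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.sigma <= 0 or self.k0 <= 0 or self.d0 < 0:
            raise ValueError("sigma and k0 must be positive, d0 non-negative")
        for name in ("r0", "a0", "u0", "collapse_area", "smoothing_radius",
                     "max_recursion", "sc_isolation_px"):
            v = getattr(self, name)
            if int(v) != v or v < 1:
                raise ValueError(f"{name} must be a positive integer")
        if not 1 <= self.u0 <= 10:
            raise ValueError("u0 must lie in 1..10")
        if any(n < 1 or int(n) != n for n in self.n0_list):
            raise ValueError("n0_list entries must be positive integers")
        if self.labeling_mode not in ("argmax", "kmeans"):
            raise ValueError("labeling_mode must be 'argmax' or 'kmeans'")
        for name in ("membrane_support_frac", "nucleus_free_overlap_tol",
                     "nucleus_free_min_solidity"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")

    def replace(self, **kwargs) -> "UnsegParams":
        return replace(self, **kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "UnsegParams":
        """Read parameters from a plain-text ``key = value`` file.

        Keys mirror the field names exactly; ``n0_list`` is a
        comma-separated list. Lines starting with ``#`` are ignored.
        """
        known = {f.name: f for f in fields(cls)}
        kwargs: dict = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {raw!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise ValueError(f"unknown parameter {key!r}")
            if key == "n0_list":
                kwargs[key] = tuple(int(v) for v in value.split(","))
            elif key == "labeling_mode":
                kwargs[key] = value
            elif key in ("r0", "a0", "u0", "collapse_area", "smoothing_radius",
                         "max_recursion", "rng_seed", "sc_isolation_px"):
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)


def normalize_channel(arr: np.ndarray) -> np.ndarray:
    """Min-max scale one channel to [0, 1]; a constant channel maps to zeros."""
    arr = np.asarray(arr, dtype=float)
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def _read_plane(path: Path, index: int | None) -> np.ndarray:
    data = tifffile.imread(path)
    if data.ndim == 2:
        if index not in (None, 0):
            raise IndexError(f"{path} has a single plane; index {index} invalid")
        return data
    if data.ndim == 3:
        if index is None:
            raise IndexError(f"{path} is multi-plane; a channel index is required")
        if not 0 <= index < data.shape[0]:
            raise IndexError(f"channel index {index} out of range for {path}")
        return data[index]
    raise IOError(f"{path}: unsupported TIFF dimensionality {data.ndim}")


def load_two_channel_image(
    path_or_paths: str | Path | Sequence[str | Path],
    nucleus_index: int = 0,
    membrane_index: int = 1,
    pixel_pitch: float | None = None,
) -> TwoChannelImage:
    """Load a two-channel image from one multi-plane TIFF or two TIFFs.

    Each channel is independently min-max normalized to ``[0, 1]``.
    """
    if isinstance(path_or_paths, (str, Path)):
        p = Path(path_or_paths)
        nuc = _read_plane(p, nucleus_index)
        mem = _read_plane(p, membrane_index)
    else:
        paths = [Path(p) for p in path_or_paths]
        if len(paths) != 2:
            raise IOError("expected one multi-plane TIFF or exactly two TIFFs")
        nuc = _read_plane(paths[0], None)
        mem = _read_plane(paths[1], None)
    if nuc.shape != mem.shape:
        raise ValueError(f"channel shapes differ: {nuc.shape} vs {mem.shape}")
    return TwoChannelImage(
        nucleus=normalize_channel(nuc),
        membrane=normalize_channel(mem),
        pixel_pitch=pixel_pitch,
    )


def relabel_raster_order(labels: np.ndarray) -> np.ndarray:
    """Relabel instances 1..N in raster order of each id's first pixel."""
    labels = np.asarray(labels)
    flat = labels.ravel()
    nonzero = np.flatnonzero(flat)
    if nonzero.size == 0:
        return labels.astype(np.int64, copy=True)
    # first occurrence of each id in raster order
    ids, first = np.unique(flat[nonzero], return_index=True)
    order = np.argsort(nonzero[first])
    lut = np.zeros(int(flat.max()) + 1, dtype=np.int64)
    lut[ids[order]] = np.arange(1, ids.size + 1)
    return lut[labels]


def _label_dtype(labels: np.ndarray) -> np.dtype:
    if labels.max(initial=0) > np.iinfo(np.uint16).max:
        logger.warning("more than 65535 objects; promoting label TIFF to 32-bit")
        return np.dtype(np.uint32)
    return np.dtype(np.uint16)


def _object_table(labels: np.ndarray, kind: str,
                  partner: dict[int, int] | None = None) -> pd.DataFrame:
    rows = []
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size:
        coms = ndi.center_of_mass(labels > 0, labels, ids)
        areas = ndi.sum_labels(np.ones_like(labels, dtype=np.int64), labels, ids)
        for oid, com, area in zip(ids, coms, areas):
            rows.append({
                "id": int(oid),
                "kind": kind,
                "area_px": int(area),
                "centroid_row": float(com[0]),
                "centroid_col": float(com[1]),
                "partner_id": int((partner or {}).get(int(oid), 0)),
            })
    return pd.DataFrame(
        rows,
        columns=["id", "kind", "area_px", "centroid_row", "centroid_col",
                 "partner_id"],
    )


def write_outputs(
    nuclei: np.ndarray,
    cells: np.ndarray,
    out_dir: str | Path,
    nucleus_to_cell: dict[int, int] | None = None,
) -> dict[str, Path]:
    """Write nucleus/cell label TIFFs and a combined object table CSV.

    The object table has one row per object with columns
    ``id, kind, area_px, centroid_row, centroid_col, partner_id`` where
    ``partner_id`` links a nucleus to its cell and vice versa (0 = none).
    """
    nuclei = np.asarray(nuclei)
    cells = np.asarray(cells)
    if nuclei.shape != cells.shape:
        raise ValueError("nucleus and cell label maps must share a shape")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "nuclei": out / "nuclei.tif",
        "cells": out / "cells.tif",
        "objects": out / "objects.csv",
    }
    tifffile.imwrite(paths["nuclei"], nuclei.astype(_label_dtype(nuclei)))
    tifffile.imwrite(paths["cells"], cells.astype(_label_dtype(cells)))
    n2c = nucleus_to_cell or {}
    c2n = {c: n for n, c in n2c.items()}
    table = pd.concat(
        [_object_table(nuclei, "nucleus", n2c), _object_table(cells, "cell", c2n)],
        ignore_index=True,
    )
    table.to_csv(paths["objects"], index=False)
    return paths


def validate_probability_field(values: np.ndarray, name: str = "field") -> None:
    """Raise unless ``values`` is a finite 2D grid in [0, 1]."""
    v = np.asarray(values)
    if v.ndim != 2:
        raise ValueError(f"{name} must be 2D")
    if not np.isfinite(v).all() or v.min() < 0 or v.max() > 1:
        raise ValueError(f"{name} must lie in [0, 1]")


def validate_semantic_labels(values: np.ndarray, name: str = "labels") -> None:
    """Raise unless ``values`` is a 2D grid over {0, 1, 2}."""
    v = np.asarray(values)
    if v.ndim != 2 or not np.isin(v, (0, 1, 2)).all():
        raise ValueError(f"{name} must be a 2D grid over {{0, 1, 2}}")
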