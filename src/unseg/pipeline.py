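"""End-to-end orchestration of the four processing stages.

``run_unseg`` executes stage 1 (priors) through stage 4 (cells) on a
two-channel image, asserts the pipeline invariants on every run (probability
bounds, posterior exclusivity, label disjointness, nucleus-within-cell
containment) and returns the instance maps plus a manifest describing the
run. ``runtime_scaling_probe`` measures how wall time grows with the number
of segmented cells on uniform-density synthetic fields.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .cell_instances import CellRecord, segment_cells
from .core_io import TwoChannelImage, UnsegParams
from .nucleus_instances import segment_nuclei
from .posterior_stage import posterior_stage_outputs
from .prior_stage import prior_stage_outputs
from .synthetic import FixtureSpec, generate_tissue

logger = logging.getLogger("unseg")

__all__ = ["RunManifest", "StageError", "run_unseg", "runtime_scaling_probe"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class RunManifest:
    """Everything needed to reconstruct a run."""

    params: dict
    version: str = __version__
    input_paths: list[str] = field(default_factory=list)
    stage_seconds: dict[str, float] = field(default_factory=dict)
    n_nuclei: int = 0
    n_cells: int = 0
    output_paths: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _assert_invariants(nuclei: np.ndarray, cells: np.ndarray,
                       post: dict) -> None:
    for name in ("P1g", "P2g", "P1l", "P2l"):
        v = post[name]
        assert v.min() >= 0.0 and v.max() <= 1.0, f"{name} out of [0, 1]"
    assert not np.any(post["P1g"] * post["P2g"]), "posterior fields overlap"
    nuc_fg = nuclei > 0
    if nuc_fg.any():
        inside = cells[nuc_fg] > 0
        assert inside.all(), "nucleus pixels outside every cell"
        # each nucleus lies inside exactly one cell
        df = pd.DataFrame({"n": nuclei[nuc_fg], "c": cells[nuc_fg]})
        per = df.groupby("n")["c"].nunique()
        assert (per == 1).all(), "a nucleus spans multiple cells"


def run_unseg(
    image: TwoChannelImage,
    params: UnsegParams | None = None,
    dump_dir: str | Path | None = None,
) -> tuple[np.ndarray, np.ndarray, RunManifest, list[CellRecord]]:
    """Run all four stages; returns (nuclei, cells, manifest, cell records).

    With ``dump_dir`` set, the intermediate fields (priors, masks,
    likelihood, semantic maps) are written as TIFFs for inspection.
    """
    params = params or UnsegParams()
    manifest = RunManifest(params=asdict(params))
    timings = manifest.stage_seconds

    def _stage(name, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except AssertionError:
            raise
        except Exception as exc:  # annotate with the failing stage
            raise StageError(name, exc) from exc
        timings[name] = time.perf_counter() - t0
        return out

    prior1 = _stage("prior_nucleus",
                    lambda: prior_stage_outputs(image.nucleus, params, params.p1))
    prior2 = _stage("prior_membrane",
                    lambda: _membrane_priors(image.membrane, params))
    post = _stage("posterior",
                  lambda: posterior_stage_outputs(image, prior1, prior2, params))
    nuclei = _stage("nuclei",
                    lambda: segment_nuclei(post["Mg"], post["Ml"], params))
    cells, records, n2c = _stage(
        "cells", lambda: segment_cells(nuclei, post["Mg"], post["P2g"], params))

    _assert_invariants(nuclei, cells, post)
    manifest.n_nuclei = int(np.unique(nuclei[nuclei > 0]).size)
    manifest.n_cells = int(np.unique(cells[cells > 0]).size)
    logger.info("pipeline: %d nuclei, %d cells", manifest.n_nuclei,
                manifest.n_cells)

    if dump_dir is not None:
        dump = Path(dump_dir)
        dump.mkdir(parents=True, exist_ok=True)
        grids = {
            "P1e": prior1["Pe"], "P2e": prior2["Pe"],
            "M1g": prior1["Mg"], "M2g": prior2["Mg"],
            "M1l": prior1["Ml"], "M2l": prior2["Ml"],
            "L": post["L"].values, "P1g": post["P1g"], "P2g": post["P2g"],
            "Mg": post["Mg"], "Ml": post["Ml"],
        }
        for name, grid in grids.items():
            tifffile.imwrite(dump / f"{name}.tif",
                             np.asarray(grid).astype(np.float32))
    return nuclei, cells, manifest, records


def _membrane_priors(I: np.ndarray, params: UnsegParams) -> dict:
    """Stage 1 for the membrane channel. An all-background membrane channel
    (no marker expressed anywhere) degrades gracefully to empty masks and a
    zero prior, which routes every cell through the dilation fallback."""
    try:
        return prior_stage_outputs(I, params, params.p2)
    except ValueError:
        logger.warning("membrane channel has no usable foreground; "
                       "falling back to empty membrane priors")
        zeros = np.zeros(I.shape)
        empty = np.zeros(I.shape, dtype=bool)
        return {"foreground": empty, "Pe": zeros, "Mg": empty, "Ml": empty}


def runtime_scaling_probe(
    cell_counts: list[int],
    template: FixtureSpec | None = None,
    params: UnsegParams | None = None,
) -> pd.DataFrame:
    """Wall time of the full pipeline vs segmented-cell count.

    Fixtures keep a uniform cell density (image area grows proportionally to
    the requested cell count). Returns a table with columns
    ``n_cells_requested, n_cells_segmented, seconds`` plus the least-squares
    ``r_squared`` of seconds vs segmented count in ``df.attrs``.
    """
    if len(cell_counts) < 3:
        raise ValueError("need at least 3 sizes")
    template = template or FixtureSpec()
    params = params or UnsegParams()
    base_area = template.shape[0] * template.shape[1]
    density = template.n_cells / base_area
    rows = []
    for n in cell_counts:
        side = int(np.sqrt(n / density))
        spec = template.replace(shape=(side, side), n_cells=int(n))
        bundle = generate_tissue(spec)
        t0 = time.perf_counter()
        _, cells, manifest, _ = run_unseg(bundle.image, params)
        dt = time.perf_counter() - t0
        rows.append({"n_cells_requested": int(n),
                     "n_cells_segmented": manifest.n_cells,
                     "seconds": dt})
    df = pd.DataFrame(rows)
    x = df["n_cells_segmented"].to_numpy(dtype=float)
    y = df["seconds"].to_numpy(dtype=float)
    coef = np.polyfit(x, y, 1)
    resid = y - np.polyval(coef, x)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else 1.0
    df.attrs["r_squared"] = r2
    df.attrs["slope_seconds_per_cell"] = float(coef[0])
    return df
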