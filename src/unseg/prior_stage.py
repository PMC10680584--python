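"""Stage 1: a-priori per-channel probability fields and foreground masks.

For each channel the stage computes

1. an initial foreground estimate (Gaussian smoothing + the lower threshold
   of a three-class Otsu),
2. the empirical intensity CDF of that foreground, evaluated image-wide as
   the a-priori probability of a pixel belonging to the channel's
   compartment,
3. a *global* mask from a multi-scale local-mean suppression filter (LMSF)
   refined by the prior probability — a deliberate superset of the true
   compartment pixels with inter-cell valleys removed, and
4. a *local* mask from a gradient-adaptive-smoothed (GAS) image thresholded
   by a local (disk-neighborhood) Otsu, restricted to the global mask.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import rank, threshold_multiotsu, threshold_otsu
from skimage.morphology import disk
from skimage.util import img_as_ubyte

from .core_io import UnsegParams

logger = logging.getLogger("unseg")

__all__ = [
    "EmpiricalCDF",
    "initial_foreground",
    "apriori_probability",
    "lmsf",
    "global_mask",
    "gas",
    "local_mask",
    "prior_stage_outputs",
]


class EmpiricalCDF:
    """Empirical cumulative distribution of a foreground intensity sample.

    ``cdf(v)`` is the fraction of sample values ``<= v``; it is monotone
    non-decreasing and equals 1 at (and above) the sample maximum.
    """

    def __init__(self, sample: np.ndarray):
        sample = np.asarray(sample, dtype=float).ravel()
        if sample.size == 0:
            raise ValueError("empty sample")
        self.sample = np.sort(sample)

    def __call__(self, values: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.sample, np.asarray(values, dtype=float),
                              side="right")
        return idx / self.sample.size


def initial_foreground(I: np.ndarray, sigma: float) -> np.ndarray:
    """Initial channel-foreground estimate.

    The channel is Gaussian-smoothed with standard deviation ``sigma`` and
    thresholded at the lower of the two thresholds of a three-class Otsu;
    pixels strictly above the threshold are foreground. Images with fewer
    than three distinct smoothed values fall back to single-threshold Otsu.
    """
    I = np.asarray(I, dtype=float)
    smoothed = ndi.gaussian_filter(I, sigma=sigma)
    distinct = np.unique(smoothed)
    if distinct.size < 2:
        return np.zeros_like(I, dtype=bool)
    if distinct.size < 3:
        logger.info("initial_foreground: <3 distinct values, using 2-class Otsu")
        thr = threshold_otsu(smoothed)
    else:
        try:
            thr = threshold_multiotsu(smoothed, classes=3)[0]
        except ValueError:
            logger.info("initial_foreground: multi-Otsu failed, using 2-class Otsu")
            thr = threshold_otsu(smoothed)
    return smoothed > thr


def apriori_probability(I: np.ndarray, fg: np.ndarray) -> np.ndarray:
    """A-priori probability field: the foreground CDF evaluated image-wide.

    Raises if the foreground estimate is empty (review sigma / threshold).
    """
    I = np.asarray(I, dtype=float)
    fg = np.asarray(fg, dtype=bool)
    if not fg.any():
        raise ValueError(
            "empty foreground estimate; review sigma or image contrast"
        )
    return EmpiricalCDF(I[fg])(I)


def lmsf(I: np.ndarray, t0: float, n0: int) -> np.ndarray:
    """Local mean suppression filter at one scale.

    A pixel is set to 0 iff its intensity divided by the mean over the
    surrounding ``(2*n0+1)**2`` window (zero-padded outside the image, the
    divisor always the full window size) falls below ``t0``; otherwise its
    value is unchanged. An all-zero neighborhood zeroes the pixel.
    """
    I = np.asarray(I, dtype=float)
    size = 2 * int(n0) + 1
    mean = ndi.uniform_filter(I, size=size, mode="constant", cval=0.0)
    keep = (mean > 0) & (I >= t0 * mean)
    return np.where(keep, I, 0.0)


def global_mask(I: np.ndarray, Pe: np.ndarray, params: UnsegParams,
                p_threshold: float) -> np.ndarray:
    """A-priori global mask: multi-scale LMSF survival refined by the prior.

    A pixel is foreground iff LMSF at *every* scale in ``params.n0_list``
    (each applied independently to the original image) leaves it nonzero and
    its prior probability is at least ``p_threshold``.
    """
    I = np.asarray(I, dtype=float)
    survived = np.ones(I.shape, dtype=bool)
    for n0 in params.n0_list:
        survived &= lmsf(I, params.t0, n0) > 0
    return survived & (np.asarray(Pe) >= p_threshold)


def _replicated_gradient(I: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Central differences with edge-replicated borders."""
    P = np.pad(I, 1, mode="edge")
    gr = (P[2:, 1:-1] - P[:-2, 1:-1]) / 2.0
    gc = (P[1:-1, 2:] - P[1:-1, :-2]) / 2.0
    return gr, gc


def gas(I: np.ndarray, k0: float) -> np.ndarray:
    """One iteration of gradient adaptive smoothing.

    Each pixel becomes the 3x3 weighted mean of its neighborhood with
    weights ``w = exp(-d^2 / (2 k0^2))`` where ``d`` is the gradient
    magnitude (central differences, replicated borders). Flat regions are
    smoothed; strong edges receive near-zero weight and are preserved.
    """
    I = np.asarray(I, dtype=float)
    gr, gc = _replicated_gradient(I)
    w = np.exp(-(gr * gr + gc * gc) / (2.0 * k0 * k0))
    Ip = np.pad(I, 1, mode="edge")
    wp = np.pad(w, 1, mode="edge")
    num = np.zeros_like(I)
    den = np.zeros_like(I)
    H, W = I.shape
    for dr in (0, 1, 2):
        for dc in (0, 1, 2):
            wshift = wp[dr:dr + H, dc:dc + W]
            num += Ip[dr:dr + H, dc:dc + W] * wshift
            den += wshift
    return num / den


def local_mask(I_gas: np.ndarray, r0: int, Mg_channel: np.ndarray) -> np.ndarray:
    """A-priori local mask: local Otsu of the GAS image, limited to M^g.

    The threshold at each pixel is the Otsu threshold of the 8-bit
    quantized intensities within a disk of radius ``r0``; pixels strictly
    above their local threshold are foreground. Zero-variance neighborhoods
    yield background. The result is intersected with the channel's global
    mask, which suppresses spurious responses over tissue-free background.
    """
    I_gas = np.asarray(I_gas, dtype=float)
    u8 = img_as_ubyte(np.clip(I_gas, 0.0, 1.0))
    thr = rank.otsu(u8, disk(int(r0)))
    return (u8 > thr) & np.asarray(Mg_channel, dtype=bool)


def prior_stage_outputs(I: np.ndarray, params: UnsegParams,
                        p_threshold: float) -> dict[str, np.ndarray]:
    """Run stage 1 for one channel; returns Pe, Mg and Ml."""
    fg = initial_foreground(I, params.sigma)
    Pe = apriori_probability(I, fg)
    Mg = global_mask(I, Pe, params, p_threshold)
    Ml = local_mask(gas(I, params.k0), params.r0, Mg)
    return {"foreground": fg, "Pe": Pe, "Mg": Mg, "Ml": Ml}
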