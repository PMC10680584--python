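"""Stage 2: contrast likelihood and a-posteriori semantic label maps.

The two channels are fused Bayesian-style: a signed visual-contrast
likelihood ``L`` in [-1, 1] (negative = nucleus evidence, positive =
membrane evidence) is combined with the saturated a-priori probabilities
into mutually exclusive posterior fields, which are then collapsed into a
3-class semantic map (0 background, 1 nucleus, 2 membrane) by arg-max or
k-means labeling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_io import TwoChannelImage, UnsegParams

logger = logging.getLogger("unseg")

__all__ = [
    "LikelihoodMap",
    "contrast_likelihood",
    "saturate_prior",
    "posterior_global",
    "posterior_local",
    "semantic_labels",
    "posterior_stage_outputs",
]


@dataclass(frozen=True)
class LikelihoodMap:
    """Signed contrast likelihood with the channel minima used to gate it."""

    values: np.ndarray
    i1: float
    i2: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or np.abs(v).max(initial=0.0) > 1.0:
            raise ValueError("likelihood must be a 2D grid in [-1, 1]")
        object.__setattr__(self, "values", v)


def _support_min(I: np.ndarray, Ml: np.ndarray, name: str) -> float:
    Ml = np.asarray(Ml, dtype=bool)
    if not Ml.any():
        logger.warning("empty local-mask support for %s; using i=0", name)
        return 0.0
    return float(I[Ml].min())


def contrast_likelihood(
    img: TwoChannelImage,
    M1l: np.ndarray,
    M2l: np.ndarray,
    M1g: np.ndarray,
    M2g: np.ndarray,
) -> LikelihoodMap:
    """Contrast-based likelihood of nucleus vs membrane identity.

    ``L0 = (I2 - I1) / (I2 + I1)`` wherever either channel exceeds its
    local-mask minimum intensity (else 0); the likelihood ``L`` keeps
    negative values only inside the nucleus global mask and positive values
    only inside the membrane global mask.
    """
    I1, I2 = img.nucleus, img.membrane
    i1 = _support_min(I1, M1l, "nucleus")
    i2 = _support_min(I2, M2l, "membrane")
    qualifies = (I1 > i1) | (I2 > i2)
    total = I1 + I2
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, (I2 - I1) / np.where(total > 0, total, 1.0), 0.0)
    L0 = np.where(qualifies, ratio, 0.0)
    M1g = np.asarray(M1g, dtype=bool)
    M2g = np.asarray(M2g, dtype=bool)
    keep = ((L0 < 0) & M1g) | ((L0 > 0) & M2g)
    return LikelihoodMap(values=np.where(keep, L0, 0.0), i1=i1, i2=i2)


def saturate_prior(Pe: np.ndarray, Ml: np.ndarray) -> np.ndarray:
    """Saturated prior: probability forced to 1 on the local-mask support."""
    return np.where(np.asarray(Ml, dtype=bool), 1.0, np.asarray(Pe, dtype=float))


def posterior_global(
    P1s: np.ndarray, P2s: np.ndarray, L: LikelihoodMap
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior global probabilities: likelihood-weighted convex combination.

    ``P1g = P1s + (1 - P1s)|L|`` where ``L < 0`` (else 0) and symmetrically
    for the membrane where ``L > 0``; by construction ``P1g * P2g = 0``
    everywhere.
    """
    Lv = L.values
    absL = np.abs(Lv)
    P1s = np.asarray(P1s, dtype=float)
    P2s = np.asarray(P2s, dtype=float)
    P1g = np.where(Lv < 0, P1s + (1.0 - P1s) * absL, 0.0)
    P2g = np.where(Lv > 0, P2s + (1.0 - P2s) * absL, 0.0)
    return P1g, P2g


def posterior_local(
    P1e: np.ndarray, P2e: np.ndarray, M1l: np.ndarray, M2l: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior local probabilities: priors restricted to local masks."""
    P1l = np.where(np.asarray(M1l, dtype=bool), np.asarray(P1e, dtype=float), 0.0)
    P2l = np.where(np.asarray(M2l, dtype=bool), np.asarray(P2e, dtype=float), 0.0)
    return P1l, P2l


def _kmeans_labels(P1: np.ndarray, P2: np.ndarray, seed: int) -> np.ndarray:
    from sklearn.cluster import KMeans

    fg = (P1 > 0) | (P2 > 0)
    out = np.zeros(P1.shape, dtype=np.uint8)
    if not fg.any():
        return out
    X = np.column_stack([P1[fg], P2[fg]])
    init = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
    n_unique = np.unique(X, axis=0).shape[0]
    if n_unique < 3:
        # degenerate feature cloud: fall back to arg-max labeling
        return _argmax_labels(P1, P2)
    km = KMeans(n_clusters=3, init=init, n_init=1, random_state=seed).fit(X)
    # a cluster votes nucleus or membrane by its dominant center coordinate;
    # the background constraint was already applied to (0, 0) pixels above
    centers = km.cluster_centers_
    class_of = np.where(centers[:, 0] >= centers[:, 1], 1, 2)
    labels = class_of[km.labels_]
    out[fg] = labels
    return out


def _argmax_labels(P1: np.ndarray, P2: np.ndarray) -> np.ndarray:
    out = np.zeros(P1.shape, dtype=np.uint8)
    out[(P1 >= P2) & (P1 > 0)] = 1  # ties P1 == P2 > 0 favor the nucleus
    out[P2 > P1] = 2
    return out


def semantic_labels(
    P1: np.ndarray,
    P2: np.ndarray,
    mode: str = "argmax",
    seed: int = 0,
) -> np.ndarray:
    """Collapse a pair of probability fields into a 3-class semantic map.

    Pixels where both probabilities are zero are hard-assigned to the
    background before labeling. ``argmax`` (default) labels by the larger
    probability (ties broken toward the nucleus to protect downstream
    seeding); ``kmeans`` clusters the (P1, P2) pairs into three groups with
    canonical initial centers (0,0), (1,0), (0,1).
    """
    P1 = np.asarray(P1, dtype=float)
    P2 = np.asarray(P2, dtype=float)
    if P1.shape != P2.shape:
        raise ValueError("probability fields must share a shape")
    if mode == "argmax":
        return _argmax_labels(P1, P2)
    if mode == "kmeans":
        return _kmeans_labels(P1, P2, seed)
    raise ValueError(f"unknown labeling mode {mode!r}")


def posterior_stage_outputs(
    img: TwoChannelImage,
    prior1: dict[str, np.ndarray],
    prior2: dict[str, np.ndarray],
    params: UnsegParams,
) -> dict[str, np.ndarray]:
    """Run stage 2 from the two channels' stage-1 outputs.

    Returns the likelihood, the posterior global/local probability pairs and
    the global/local semantic label maps ``Mg`` / ``Ml``.
    """
    L = contrast_likelihood(img, prior1["Ml"], prior2["Ml"],
                            prior1["Mg"], prior2["Mg"])
    P1s = saturate_prior(prior1["Pe"], prior1["Ml"])
    P2s = saturate_prior(prior2["Pe"], prior2["Ml"])
    P1g, P2g = posterior_global(P1s, P2s, L)
    P1l, P2l = posterior_local(prior1["Pe"], prior2["Pe"],
                               prior1["Ml"], prior2["Ml"])
    Mg = semantic_labels(P1g, P2g, params.labeling_mode, params.rng_seed)
    Ml = semantic_labels(P1l, P2l, params.labeling_mode, params.rng_seed)
    return {"L": L, "P1g": P1g, "P2g": P2g, "P1l": P1l, "P2l": P2l,
            "Mg": Mg, "Ml": Ml}
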