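"""Dehazing-style scatter correction baseline (Meng et al.).

The correction treats scatter as atmospheric haze:

    I_corr(x) = (I(x) - A) / max(t(x), eps)**delta + A

with A the scatter floor of a region of interest (its minimum intensity),
t(x) a transmission map in (0, 1] describing the primary fluence, eps a
small positive floor against division by zero, and delta an empirical
exponent tuned per region (global / lung / spine).

The original method recovers t(x) by an ADMM contrast-maximisation; here a
simplified surrogate is provided instead — a smoothed, range-normalised
intensity mapped into (C0/C1, 1] — which preserves the properties the
correction depends on (smoothness, monotonicity in intensity, scale
invariance) without the optimiser.  The correction formula itself is exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml
from scipy import ndimage

__all__ = [
    "MengParams",
    "meng_correct",
    "meng_invert",
    "estimate_transmission",
    "ambient_from_roi",
    "load_table_defaults",
]


@dataclass(frozen=True)
class MengParams:
    """Parameters of the dehazing correction for one region of interest."""

    A: float
    delta: float = 0.3
    epsilon: float = 1e-8
    C0: float = 1.0
    C1: float = 4.8
    lam: float = 1.0

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not 0 <= self.C0 < self.C1:
            raise ValueError("require 0 <= C0 < C1")
        if self.delta <= 0:
            raise ValueError("delta must be positive")


def load_table_defaults(dataset: str = "SimPBU100", region: str = "global") -> MengParams:
    """Published parameterisation of the baseline, per dataset and region.

    ``dataset`` is one of SimPBU100, SimPat120, RePBU100; ``region`` one of
    global, lung, spine.  The A and delta values were tuned against ground
    truth per region in the original comparison.
    """
    with resources.files("bsscatter.data").joinpath("meng_table1.yaml").open() as fh:
        table = yaml.safe_load(fh)
    try:
        row = table[dataset]
    except KeyError as e:
        raise KeyError(f"unknown dataset {dataset!r}; have {sorted(table)}") from e
    if region not in ("global", "lung", "spine"):
        raise KeyError(f"unknown region {region!r}")
    return MengParams(
        A=row[f"A_{region}"],
        delta=row[f"delta_{region}"],
        epsilon=row["epsilon"],
        C0=row["C0"],
        C1=row["C1"],
        lam=row["lambda"],
    )


def ambient_from_roi(img: np.ndarray, roi_mask: np.ndarray | None = None) -> float:
    """Scatter floor A: the minimum intensity inside the region of interest."""
    img = np.asarray(img, dtype=float)
    if roi_mask is None:
        return float(img.min())
    return float(img[np.asarray(roi_mask, bool)].min())


def meng_correct(img: np.ndarray, t_map: np.ndarray, p: MengParams) -> np.ndarray:
    """Apply the dehazing correction pixelwise.

    ``I_corr = (I - A) / max(t, eps)**delta + A``.  With ``t == 1``
    everywhere this is the identity for any delta.
    """
    img = np.asarray(img, dtype=float)
    t_map = np.asarray(t_map, dtype=float)
    if img.shape != t_map.shape:
        raise ValueError("t_map must be congruent with the image")
    denom = np.maximum(t_map, p.epsilon) ** p.delta
    return (img - p.A) / denom + p.A


def meng_invert(corrected: np.ndarray, t_map: np.ndarray, p: MengParams) -> np.ndarray:
    """Exact inverse of :func:`meng_correct` given the same t, A, delta."""
    corrected = np.asarray(corrected, dtype=float)
    denom = np.maximum(np.asarray(t_map, float), p.epsilon) ** p.delta
    return (corrected - p.A) * denom + p.A


def estimate_transmission(
    img: np.ndarray,
    C0: float = 1.0,
    C1: float = 4.8,
    smoothing_scale_px: float = 25.0,
) -> np.ndarray:
    """Simplified transmission surrogate (NOT the original ADMM optimiser).

    A Gaussian low-pass of the image is range-normalised to [0, 1] and
    affinely mapped to (C0/C1, 1].  The map is smooth at the requested
    scale, monotone in the image intensity and invariant to a positive
    rescaling of the input.  A constant image yields a uniform t of 1.
    """
    if C1 <= C0:
        raise ValueError("require C1 > C0")
    img = np.asarray(img, dtype=float)
    s = ndimage.gaussian_filter(img, smoothing_scale_px, mode="nearest")
    lo, hi = float(s.min()), float(s.max())
    if hi <= lo:
        return np.ones_like(img)
    u = (s - lo) / (hi - lo)
    return (C0 + u * (C1 - C0)) / C1
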