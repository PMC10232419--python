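"""Evaluation metrics for scatter-corrected radiographs.

All inter-image comparisons run on percentile-normalised images so that
methods producing different dynamic ranges can be compared: the image is
shifted by the mean of its sub-2nd-percentile tail and scaled by the spread
between the two tail means.  Metrics are then ROI-based: root-mean-square
error against the ground truth in lung/spine regions, mean/std SNR in a
homogeneous (liver) region, lung-heart contrast recovery, and line
profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ROISpec",
    "normalize_range",
    "rmse_roi",
    "snr_roi",
    "contrast_recovery",
    "extract_profile",
    "default_rois",
]


@dataclass(frozen=True)
class ROISpec:
    """Rectangular region of interest: name, top-left corner, size in px."""

    name: str
    top_left: tuple[int, int]
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("ROI must be at least 1x1")
        if self.top_left[0] < 0 or self.top_left[1] < 0:
            raise ValueError("ROI corner must be nonnegative")

    def slices(self, shape: tuple[int, int]) -> tuple[slice, slice]:
        r, c = self.top_left
        if r + self.height > shape[0] or c + self.width > shape[1]:
            raise ValueError(f"ROI {self.name!r} exceeds image bounds {shape}")
        return slice(r, r + self.height), slice(c, c + self.width)

    def extract(self, img: np.ndarray) -> np.ndarray:
        sr, sc = self.slices(img.shape)
        return img[sr, sc]


def default_rois(shape: tuple[int, int]) -> dict[str, ROISpec]:
    """Chest-layout ROIs scaled to the image: lung/spine RMSE regions and
    128x128-equivalent SNR/contrast patches in lung, heart and liver.

    Placements follow the default chest phantom (lungs upper lateral, heart
    left-central, spine on the midline, liver lower right); they are
    starting points, not anatomy detection.
    """
    r, c = shape
    sq = max(4, int(round(0.03 * r)))  # 128 px on a 4288-row detector

    def roi(name, rc, cc, h, w):
        return ROISpec(name, (int(rc - h / 2), int(cc - w / 2)), h, w)

    return {
        "lung": roi("lung", 0.44 * r, 0.30 * c, sq, sq),
        "heart": roi("heart", 0.60 * r, 0.44 * c, sq, sq),
        "liver": roi("liver", 0.76 * r, 0.67 * c, sq, sq),
        "lung_rmse": roi("lung_rmse", 0.44 * r, 0.30 * c, int(0.13 * r), int(0.23 * c)),
        "spine_rmse": roi("spine_rmse", 0.50 * r, 0.50 * c, int(0.47 * r), max(4, int(0.05 * c))),
        "global": ROISpec("global", (0, 0), r, c),
    }


def normalize_range(img: np.ndarray) -> np.ndarray:
    """Normalise to the dynamic range between the percentile-tail means.

    Subtracts the mean of pixels below the 2nd percentile and divides by
    the spread to the mean of pixels above the 98th percentile — a robust
    min/max that ignores outliers.  Affine-invariant: a*img + b (a > 0)
    normalises to the same output.
    """
    img = np.asarray(img, dtype=float)
    p2, p98 = np.percentile(img, [2.0, 98.0])
    low = img[img < p2]
    high = img[img > p98]
    # ties at the percentile (e.g. a flat unattenuated background) can empty
    # the strict tail; fall back to the inclusive one
    if low.size == 0:
        low = img[img <= p2]
    if high.size == 0:
        high = img[img >= p98]
    lo = low.mean()
    hi = high.mean()
    if hi - lo <= 0:
        raise ValueError("near-constant image: nonpositive normalisation span")
    return (img - lo) / (hi - lo)


def rmse_roi(a: np.ndarray, b: np.ndarray, roi: ROISpec, normalize: bool = True) -> float:
    """Root-mean-square difference inside the ROI.

    By default both images are range-normalised first so images with
    different dynamic ranges compare fairly; pass ``normalize=False`` for a
    raw pixel-space RMSE.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must be congruent")
    if normalize:
        a = normalize_range(a)
        b = normalize_range(b)
    d = roi.extract(a) - roi.extract(b)
    if d.size == 0:
        raise ValueError("empty ROI")
    return float(np.sqrt(np.mean(d * d)))


def snr_roi(img: np.ndarray, roi: ROISpec) -> float:
    """Mean over population standard deviation of the ROI pixels."""
    v = roi.extract(np.asarray(img, dtype=float))
    sd = v.std()  # population (n) std
    if sd == 0:
        raise ValueError("constant ROI: SNR undefined")
    return float(v.mean() / sd)


def contrast_recovery(
    corrected: np.ndarray,
    ground_truth: np.ndarray,
    roi_lung: ROISpec,
    roi_heart: ROISpec,
    normalize: bool = True,
) -> float:
    """Lung-heart contrast of the corrected image as a fraction of truth.

    Contrast is the difference of ROI means; scatter haze compresses it, so
    an uncorrected image scores below 1 and a perfect correction scores 1.
    """
    corrected = np.asarray(corrected, dtype=float)
    ground_truth = np.asarray(ground_truth, dtype=float)
    if normalize:
        corrected = normalize_range(corrected)
        ground_truth = normalize_range(ground_truth)
    c_corr = roi_lung.extract(corrected).mean() - roi_heart.extract(corrected).mean()
    c_gt = roi_lung.extract(ground_truth).mean() - roi_heart.extract(ground_truth).mean()
    if c_gt == 0:
        raise ValueError("ground-truth contrast is zero")
    return float(c_corr / c_gt)


def extract_profile(
    img: np.ndarray,
    start: tuple[float, float],
    end: tuple[float, float],
    width: int = 1,
    pixel_mm: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean intensity across ``width`` perpendicular pixels along a line.

    Returns ``(positions_mm, values)`` with positions measured from the
    start point.  Endpoints must lie inside the image.
    """
    from scipy.ndimage import map_coordinates

    img = np.asarray(img, dtype=float)
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    for p in (start, end):
        if not (0 <= p[0] <= img.shape[0] - 1 and 0 <= p[1] <= img.shape[1] - 1):
            raise ValueError("profile endpoints must lie inside the image")
    d = end - start
    length = float(np.hypot(*d))
    if length == 0:
        raise ValueError("degenerate profile: start equals end")
    n = int(np.ceil(length)) + 1
    t = np.linspace(0.0, 1.0, n)
    line = start[None, :] + t[:, None] * d[None, :]
    perp = np.array([-d[1], d[0]]) / length
    offs = np.arange(width) - (width - 1) / 2.0
    vals = np.zeros(n)
    for o in offs:
        pts = line + o * perp[None, :]
        vals += map_coordinates(img, [pts[:, 0], pts[:, 1]], order=1, mode="nearest")
    vals /= len(offs)
    return t * length * pixel_mm, vals
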