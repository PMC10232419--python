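"""Five-step beam-stopper scatter estimation and correction.

Given a full-field projection I_ff and a projection I_BS partially
obstructed by the perforated plate:

0. both images are block-mean downsampled (default x8) — scatter is
   low-frequency, so this costs nothing and speeds up the 2D fits;
1. the obstructed image is Otsu-binarized into hole and shadow regions;
   circle-mean samples taken in the deep shadow carry the REDUCED scatter
   only, and a 2D LOESS fit of them yields the reduced scatter map S';
2. subtracting S' from the obstructed image at the hole sites leaves an
   estimate of the primary signal there;
3. subtracting that primary estimate from the downsampled full-field image
   gives samples of the FULL scatter at the hole sites;
4. a second LOESS fit interpolates those samples over the whole grid and
   the result is upsampled to full resolution -> the scatter map I_s;
5. I_s is subtracted from I_ff (negative I_s pixels clamped to zero first:
   scatter is physically nonnegative).

Hole positions are recovered from the image itself: centroids of the Otsu
components are snapped to the plate's projected square lattice, and lattice
nodes whose holes are too dark for the global threshold (behind the
mediastinum) are filled in from the fitted lattice.  Shadow samples sit at
the diagonal midpoints of the lattice, the points farthest from any hole.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.transform import resize
from scipy import ndimage

from .geometry import AcquisitionGeometry, BeamStopperSpec, projected_hole_lattice
from .loess2d import LoessConfig, loess_fit

__all__ = [
    "CorrectionConfig",
    "SampleSet",
    "CorrectionResult",
    "downsample",
    "upsample",
    "otsu_threshold",
    "binarize_otsu",
    "extract_samples",
    "estimate_scatter",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrectionConfig:
    """Tuning of the correction pipeline.

    ``downsample_factor`` 8 matches the native 0.1 mm detector; runs on
    already-coarse grids should lower it so the projected holes stay
    resolvable.  ``radius_fraction`` shrinks sampling circles below the
    projected hole radius to stay clear of the penumbra.  ``loess_span`` is
    shared by both LOESS fits.  ``exposure_ratio`` rescales I_BS when the
    two exposures were not acquired with the same mAs.
    """

    downsample_factor: int = 8
    radius_fraction: float = 0.6
    loess_span: float = 0.01
    clamp_negative_scatter: bool = True
    exposure_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.downsample_factor < 1:
            raise ValueError("downsample_factor must be >= 1")
        if not 0 < self.radius_fraction < 1:
            raise ValueError("radius_fraction must lie in (0, 1)")
        if not 0 < self.loess_span <= 1:
            raise ValueError("loess_span must lie in (0, 1]")
        if self.exposure_ratio <= 0:
            raise ValueError("exposure_ratio must be positive")


@dataclass
class SampleSet:
    """Circle-mean samples from the downsampled obstructed projection."""

    rows: np.ndarray  # centre row (float px, downsampled grid)
    cols: np.ndarray
    values: np.ndarray  # disk-mean intensity
    kinds: np.ndarray  # 'hole' | 'shadow'
    circle_radius_px: float

    def subset(self, kind: str) -> "SampleSet":
        m = self.kinds == kind
        return SampleSet(self.rows[m], self.cols[m], self.values[m], self.kinds[m], self.circle_radius_px)

    def __len__(self) -> int:
        return self.rows.size


@dataclass
class CorrectionResult:
    """Corrected image plus every intermediate of the five steps."""

    corrected: np.ndarray  # I_C = I_ff - clamped scatter map
    scatter_estimate: np.ndarray  # I_s after clamping, full resolution
    scatter_estimate_raw: np.ndarray  # I_s before clamping (conservation holds with this)
    reduced_scatter_fit: np.ndarray  # S' on the downsampled grid
    bs_primary: np.ndarray  # I_BS_small - S' (primary estimate, downsampled)
    holes_scatter: np.ndarray  # full-scatter samples at the hole sites
    mask: np.ndarray  # Otsu hole/shadow mask (downsampled grid)
    samples: SampleSet

    @property
    def corrected_raw(self) -> np.ndarray:
        """Correction without the nonnegativity clamp on the scatter map."""
        return self.corrected + self.scatter_estimate - self.scatter_estimate_raw


def downsample(img: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean reduction; trailing partial blocks average what is there."""
    img = np.asarray(img, dtype=float)
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return img.copy()
    if factor > img.shape[0] or factor > img.shape[1]:
        raise ValueError("factor exceeds an image dimension")
    edges0 = np.arange(0, img.shape[0], factor)
    edges1 = np.arange(0, img.shape[1], factor)
    s = np.add.reduceat(np.add.reduceat(img, edges0, axis=0), edges1, axis=1)
    n0 = np.diff(np.append(edges0, img.shape[0]))
    n1 = np.diff(np.append(edges1, img.shape[1]))
    return s / (n0[:, None] * n1[None, :])


def upsample(img_small: np.ndarray, target_shape: tuple[int, int]) -> np.ndarray:
    """Bicubic interpolation to ``target_shape``; constants are preserved."""
    img_small = np.asarray(img_small, dtype=float)
    if target_shape[0] < img_small.shape[0] or target_shape[1] < img_small.shape[1]:
        raise ValueError("target must be at least as large as the source")
    if img_small.shape == tuple(target_shape):
        return img_small.copy()
    if img_small.size == 1:
        return np.full(target_shape, float(img_small.flat[0]))
    return resize(img_small, target_shape, order=3, mode="edge", anti_aliasing=False)


def otsu_threshold(img: np.ndarray) -> float:
    """Otsu threshold over a 256-bin histogram (between-class variance)."""
    img = np.asarray(img, dtype=float)
    if np.ptp(img) == 0:
        raise ValueError("constant image: no threshold exists")
    return float(threshold_otsu(img, nbins=256))


def binarize_otsu(img: np.ndarray) -> np.ndarray:
    """Binarize: pixels above the Otsu threshold (the brighter class = holes)."""
    return np.asarray(img, dtype=float) > otsu_threshold(img)


def _disk_mean(img: np.ndarray, row: float, col: float, radius: float) -> float:
    r0 = max(int(np.floor(row - radius)), 0)
    r1 = min(int(np.ceil(row + radius)) + 1, img.shape[0])
    c0 = max(int(np.floor(col - radius)), 0)
    c1 = min(int(np.ceil(col + radius)) + 1, img.shape[1])
    rr, cc = np.mgrid[r0:r1, c0:c1]
    inside = (rr - row) ** 2 + (cc - col) ** 2 <= radius * radius
    if not inside.any():
        return float(img[int(round(row)), int(round(col))])
    return float(img[r0:r1, c0:c1][inside].mean())


def _circle_inside(shape: tuple[int, int], row: float, col: float, radius: float) -> bool:
    return (
        row - radius >= -0.5
        and col - radius >= -0.5
        and row + radius <= shape[0] - 0.5
        and col + radius <= shape[1] - 0.5
    )


def _circular_mean(values: np.ndarray, period: float) -> float:
    ang = 2.0 * np.pi * values / period
    return float((np.angle(np.mean(np.exp(1j * ang))) / (2.0 * np.pi) * period) % period)


def extract_samples(
    i_bs_small: np.ndarray,
    mask: np.ndarray,
    geom: AcquisitionGeometry,
    bs: BeamStopperSpec,
    radius_fraction: float = 0.6,
    downsample_factor: int = 1,
) -> SampleSet:
    """Circle-mean samples from holes and deep shadow of the obstructed image.

    The centroids of the connected components of the Otsu mask register the
    projected square lattice (its translation is unknown a priori); hole
    circles are then placed on every fitted lattice node, which also covers
    holes too dark for the global threshold (e.g. behind the mediastinum)
    and is insensitive to centroid distortion at sharp intensity edges.
    Shadow sites are the diagonal midpoints of the lattice.  Circles of radius ``radius_fraction`` times the projected
    hole radius are used for both populations; circles that would leave the
    image (holes) or touch a hole (shadow sites) are dropped.
    """
    i_bs_small = np.asarray(i_bs_small, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if i_bs_small.shape != mask.shape:
        raise ValueError("image and mask must be congruent")
    if not 0 < radius_fraction < 1:
        raise ValueError("radius_fraction must lie in (0, 1)")

    pitch_px, hole_r_px, _ = projected_hole_lattice(geom, bs)
    pitch_px /= downsample_factor
    hole_r_px /= downsample_factor
    if pitch_px < 2.0:
        raise ValueError("projected pitch below 2 px on the working grid")
    sample_r = radius_fraction * hole_r_px

    labels, n_lab = ndimage.label(mask)
    if n_lab == 0:
        raise ValueError("no hole components found in mask")
    objects = ndimage.find_objects(labels)
    areas = ndimage.sum_labels(mask, labels, index=np.arange(1, n_lab + 1))
    centroids = np.array(ndimage.center_of_mass(mask, labels, index=np.arange(1, n_lab + 1)))
    disk_area = np.pi * hole_r_px**2
    keep = []
    n_border = 0
    for i, sl in enumerate(objects):
        touches = (
            sl[0].start == 0
            or sl[1].start == 0
            or sl[0].stop == mask.shape[0]
            or sl[1].stop == mask.shape[1]
        )
        if touches:
            n_border += 1
            continue
        if not 0.25 * disk_area <= areas[i] <= 4.0 * disk_area:
            continue
        keep.append(i)
    if n_border:
        log.info("extract_samples: dropped %d border-touching components", n_border)
    if not keep:
        raise ValueError("no usable hole components (all at border or off-size)")
    cents = centroids[keep]

    # snap to the square lattice: circular mean of centroid coords mod pitch
    off_r = _circular_mean(cents[:, 0], pitch_px)
    off_c = _circular_mean(cents[:, 1], pitch_px)
    i0 = int(np.floor((-0.5 - off_r) / pitch_px))
    i1 = int(np.ceil((mask.shape[0] - 0.5 - off_r) / pitch_px))
    j0 = int(np.floor((-0.5 - off_c) / pitch_px))
    j1 = int(np.ceil((mask.shape[1] - 0.5 - off_c) / pitch_px))
    node_r = off_r + pitch_px * np.arange(i0, i1 + 1)
    node_c = off_c + pitch_px * np.arange(j0, j1 + 1)
    grid_r, grid_c = np.meshgrid(node_r, node_c, indexing="ij")

    centers = np.stack([grid_r.ravel(), grid_c.ravel()], axis=1)
    hole_rows, hole_cols, hole_vals = [], [], []
    for cr, cc in centers:
        if _circle_inside(mask.shape, cr, cc, sample_r):
            hole_rows.append(cr)
            hole_cols.append(cc)
            hole_vals.append(_disk_mean(i_bs_small, cr, cc, sample_r))

    # shadow sites: diagonal midpoints of the lattice, farthest from holes
    centers_grid = centers.reshape(grid_r.shape + (2,))
    sh_rows, sh_cols, sh_vals = [], [], []
    for i in range(centers_grid.shape[0] - 1):
        for j in range(centers_grid.shape[1] - 1):
            quad = centers_grid[i : i + 2, j : j + 2].reshape(4, 2)
            mr, mc = quad.mean(axis=0)
            if not _circle_inside(mask.shape, mr, mc, sample_r):
                continue
            dmin = np.sqrt(((quad - (mr, mc)) ** 2).sum(axis=1)).min()
            if dmin < hole_r_px + sample_r:  # circle would graze a hole/penumbra
                continue
            sh_rows.append(mr)
            sh_cols.append(mc)
            sh_vals.append(_disk_mean(i_bs_small, mr, mc, sample_r))

    if len(hole_vals) < 6 or len(sh_vals) < 6:
        raise ValueError(
            f"too few samples (holes={len(hole_vals)}, shadow={len(sh_vals)}); "
            "plate pattern not resolvable on this grid"
        )
    rows = np.array(hole_rows + sh_rows)
    cols = np.array(hole_cols + sh_cols)
    vals = np.array(hole_vals + sh_vals)
    kinds = np.array(["hole"] * len(hole_vals) + ["shadow"] * len(sh_vals))
    log.info("extract_samples: %d hole and %d shadow samples, r=%.2f px", len(hole_vals), len(sh_vals), sample_r)
    return SampleSet(rows, cols, vals, kinds, sample_r)


def _fit_grid(rows, cols, vals, shape, cfg: LoessConfig) -> np.ndarray:
    qr, qc = np.mgrid[0 : shape[0], 0 : shape[1]]
    pts = np.stack([qr.ravel(), qc.ravel()], axis=1).astype(float)
    smp = np.stack([rows, cols, vals], axis=1)
    return loess_fit(smp, pts, cfg).reshape(shape)


def estimate_scatter(
    i_ff: np.ndarray,
    i_bs: np.ndarray,
    geom: AcquisitionGeometry,
    bs: BeamStopperSpec,
    cfg: CorrectionConfig = CorrectionConfig(),
) -> CorrectionResult:
    """Run the full five-step correction. See the module docstring."""
    i_ff = np.asarray(i_ff, dtype=float)
    i_bs = np.asarray(i_bs, dtype=float) * cfg.exposure_ratio
    if i_ff.shape != i_bs.shape:
        raise ValueError("full-field and obstructed images must be congruent")

    f = cfg.downsample_factor
    ff_s = downsample(i_ff, f)
    bs_s = downsample(i_bs, f)

    mask = binarize_otsu(bs_s)
    samples = extract_samples(bs_s, mask, geom, bs, cfg.radius_fraction, f)
    holes = samples.subset("hole")
    shadows = samples.subset("shadow")
    lo = LoessConfig(span_fraction=cfg.loess_span)

    # step 1: LOESS fit of the shadow samples -> reduced scatter map S'
    s_prime = _fit_grid(shadows.rows, shadows.cols, shadows.values, bs_s.shape, lo)

    # step 2: primary estimate at the hole sites
    bs_primary = bs_s - s_prime
    s_prime_at_holes = np.array(
        [_disk_mean(s_prime, r, c, samples.circle_radius_px) for r, c in zip(holes.rows, holes.cols)]
    )
    primary_at_holes = holes.values - s_prime_at_holes

    # step 3: full scatter samples at the hole sites
    ff_at_holes = np.array(
        [_disk_mean(ff_s, r, c, samples.circle_radius_px) for r, c in zip(holes.rows, holes.cols)]
    )
    holes_scatter = ff_at_holes - primary_at_holes

    # step 4: LOESS fit over the grid, upsample to full resolution
    i_s_small = _fit_grid(holes.rows, holes.cols, holes_scatter, bs_s.shape, lo)
    i_s_raw = upsample(i_s_small, i_ff.shape)

    # step 5: clamp and subtract
    i_s = np.clip(i_s_raw, 0.0, None) if cfg.clamp_negative_scatter else i_s_raw
    corrected = i_ff - i_s

    return CorrectionResult(
        corrected=corrected,
        scatter_estimate=i_s,
        scatter_estimate_raw=i_s_raw,
        reduced_scatter_fit=s_prime,
        bs_primary=bs_primary,
        holes_scatter=holes_scatter,
        mask=mask,
        samples=samples,
    )
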