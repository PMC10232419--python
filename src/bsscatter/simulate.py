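"""Synthetic paired acquisitions of a chest-like phantom.

The forward model is deliberately simple but reproduces the two physical
facts the correction method relies on:

* the primary image is a Beer-Lambert cone-beam projection, so the shadow
  of an opaque plate carries no primary signal at all, and
* scatter is a smooth, low-frequency field generated in proportion to the
  fluence attenuated inside the patient, so blocking part of the incident
  beam with the plate reduces the scatter everywhere (the reduced field
  "scatter prime" of the obstructed exposure).

Primary transport is an exact analytic ray trace through a priority-resolved
ellipsoid phantom.  Scatter is a material-weighted convolution: the amount
of fluence absorbed in each pixel's ray, weighted by the local material's
relative Compton yield, is spread by a broad Gaussian kernel.  This is not
Monte Carlo transport; it is a stand-in with the correct low-frequency
structure and exact linearity in the incident fluence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import AcquisitionGeometry, BeamStopperSpec, project_bs_mask

__all__ = [
    "Material",
    "MATERIALS",
    "Ellipsoid",
    "PhantomSpec",
    "ScatterModelParams",
    "ProjectionImage",
    "AcquisitionSet",
    "default_chest_phantom",
    "default_geometry",
    "project_primary",
    "simulate_scatter",
    "simulate_acquisition",
    "add_poisson_noise",
]


@dataclass(frozen=True)
class Material:
    """Radiological material with single effective attenuation at ~100 kVp.

    ``scatter_yield`` is the relative scatter-source strength per unit of
    fluence attenuated in this material; tissue types scatter differently,
    which is why a single global correction factor fails in chest imaging.
    """

    name: str
    density_g_cm3: float
    mu_eff_mm_inv: float
    scatter_yield: float

    def __post_init__(self) -> None:
        if self.mu_eff_mm_inv < 0 or self.scatter_yield < 0 or self.density_g_cm3 <= 0:
            raise ValueError("material parameters must be nonnegative")


#: Default materials. Densities are standard reference values; mu_eff are
#: single effective linear attenuation coefficients at a 100 kVp spectrum
#: (~60 keV effective energy).
MATERIALS: dict[str, Material] = {
    "air": Material("air", 1.205e-3, 2.5e-5, 0.02),
    "soft_tissue": Material("soft_tissue", 1.060, 0.022, 1.0),
    "bone": Material("bone", 1.920, 0.060, 0.65),
    "tungsten": Material("tungsten", 19.299, 7.2, 0.0),
}


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid in source-centred coordinates (x, y, z), mm.

    z runs from the source (0) toward the detector (sdd); x maps to detector
    columns and y to detector rows.  Inside overlaps the ellipsoid with the
    higher ``priority`` defines the material (e.g. spine inside torso).
    """

    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    material: Material
    priority: int = 0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes_mm):
            raise ValueError("semi-axes must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    ellipsoids: tuple[Ellipsoid, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "ellipsoids", tuple(self.ellipsoids))


@dataclass(frozen=True)
class ScatterModelParams:
    """Parameters of the convolutional scatter surrogate.

    ``kernel_sigma_mm`` must be much larger than the pixel pitch — scatter
    is a low-frequency field, which is the premise that makes the 8x
    downsampling of the estimation pipeline harmless.  ``noise_photons`` is
    the expected photon count at unattenuated exposure (0 = noiseless).
    """

    kernel_sigma_mm: float = 60.0
    amplitude: float = 0.5
    noise_photons: float = 0.0

    def __post_init__(self) -> None:
        if self.kernel_sigma_mm <= 0 or self.amplitude < 0 or self.noise_photons < 0:
            raise ValueError("invalid scatter model parameters")


@dataclass
class ProjectionImage:
    """2D nonnegative intensity grid with pixel pitch and a role tag."""

    data: np.ndarray
    pixel_mm: float
    role: str = "full_field"  # full_field | bs | primary_gt | scatter_gt | corrected

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("ProjectionImage must be 2D")


@dataclass
class AcquisitionSet:
    """Outputs of one simulated paired acquisition."""

    full_field: ProjectionImage
    primary_gt: ProjectionImage
    scatter_gt: ProjectionImage
    bs_projection: ProjectionImage | None = None
    scatter_reduced_gt: ProjectionImage | None = None
    bs_mask: np.ndarray | None = None


def default_geometry(scale: int = 1) -> AcquisitionGeometry:
    """Chest acquisition geometry: 1800 mm SDD, sample 50 mm from detector.

    ``scale=1`` is the native 4288x3520 detector at 0.1 mm pitch; ``scale=8``
    gives the 536x440 grid at 0.8 mm used for desk-scale experiments (the
    same working resolution the correction pipeline reaches after its
    downsampling step at native pitch).  The plate sits next to the sample,
    so the projected pattern is only slightly magnified.
    """
    return AcquisitionGeometry(
        sdd_mm=1800.0,
        sample_to_detector_mm=50.0,
        bs_to_source_mm=1740.0,
        focal_spot_mm=1.2,
        detector_rows=4288 // scale,
        detector_cols=3520 // scale,
        pixel_mm=0.1 * scale,
    )


def default_chest_phantom(geom: AcquisitionGeometry) -> PhantomSpec:
    """Chest-like phantom: soft-tissue torso, air lungs, bone spine, heart.

    The layout provides the lung / heart / spine / liver regions that the
    evaluation metrics interrogate.  Positions are in source-centred mm; the
    torso mid-plane sits 100 mm upstream of the sample exit surface.
    """
    zc = geom.sdd_mm - geom.sample_to_detector_mm - 100.0
    soft = MATERIALS["soft_tissue"]
    air = MATERIALS["air"]
    bone = MATERIALS["bone"]
    ell = (
        Ellipsoid((0.0, 0.0, zc), (130.0, 170.0, 100.0), soft, priority=1),
        # lungs (air), slightly above centre
        Ellipsoid((-62.0, -25.0, zc), (46.0, 105.0, 62.0), air, priority=2),
        Ellipsoid((62.0, -25.0, zc), (46.0, 105.0, 62.0), air, priority=2),
        # heart: soft tissue pushed into the left lung field
        Ellipsoid((-22.0, 42.0, zc + 10.0), (44.0, 54.0, 48.0), soft, priority=3),
        # spine: elongated bone ellipsoid along the patient axis, posterior
        Ellipsoid((0.0, 0.0, zc + 45.0), (14.0, 150.0, 14.0), bone, priority=4),
    )
    return PhantomSpec(ell)


def _ray_geometry(geom: AcquisitionGeometry) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel ray vectors from the source to each detector pixel centre."""
    y, x = geom.pixel_coords_mm()
    vy = np.broadcast_to(y[:, None], (geom.detector_rows, geom.detector_cols))
    vx = np.broadcast_to(x[None, :], (geom.detector_rows, geom.detector_cols))
    vz = np.full_like(vx, geom.sdd_mm)
    return vx, vy, vz


def _path_integrals(phantom: PhantomSpec, geom: AcquisitionGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Optical depth and scatter-yield-weighted depth per detector pixel.

    Rays are parameterised as p(t) = t * v for t in [0, 1], v the vector
    from the source to the pixel.  For each ellipsoid the entry/exit t are
    the roots of a quadratic; overlaps are resolved per elementary segment
    by the highest-priority ellipsoid containing the segment midpoint.
    """
    shape = (geom.detector_rows, geom.detector_cols)
    if not phantom.ellipsoids:
        return np.zeros(shape), np.zeros(shape)
    vx, vy, vz = _ray_geometry(geom)
    ray_len = np.sqrt(vx * vx + vy * vy + vz * vz)
    n = vx.size
    ells = phantom.ellipsoids
    bounds = np.zeros((len(ells), 2, n))
    for i, e in enumerate(ells):
        cx, cy, cz = e.center_mm
        ax, ay, az = e.semi_axes_mm
        A = (vx / ax) ** 2 + (vy / ay) ** 2 + (vz / az) ** 2
        B = -2.0 * (vx * cx / ax**2 + vy * cy / ay**2 + vz * cz / az**2)
        C = (cx / ax) ** 2 + (cy / ay) ** 2 + (cz / az) ** 2 - 1.0
        disc = B * B - 4.0 * A * C
        hit = disc > 0
        sq = np.sqrt(np.where(hit, disc, 0.0))
        t0 = np.where(hit, (-B - sq) / (2.0 * A), 0.0)
        t1 = np.where(hit, (-B + sq) / (2.0 * A), 0.0)
        bounds[i, 0] = np.clip(t0, 0.0, 1.0).ravel()
        bounds[i, 1] = np.clip(t1, 0.0, 1.0).ravel()

    # sorted union of all entry/exit parameters -> elementary segments
    pts = np.sort(bounds.reshape(2 * len(ells), n), axis=0)
    ydepth = np.zeros(n)
    od = np.zeros(n)
    vxf, vyf, vzf = vx.ravel(), vy.ravel(), vz.ravel()
    for s in range(pts.shape[0] - 1):
        ta, tb = pts[s], pts[s + 1]
        dt = tb - ta
        live = dt > 0
        if not live.any():
            continue
        tm = 0.5 * (ta + tb)
        mu_seg = np.zeros(n)
        y_seg = np.zeros(n)
        best = np.full(n, -np.inf)
        px = tm * vxf
        py = tm * vyf
        pz = tm * vzf
        for e in ells:
            cx, cy, cz = e.center_mm
            ax, ay, az = e.semi_axes_mm
            inside = ((px - cx) / ax) ** 2 + ((py - cy) / ay) ** 2 + ((pz - cz) / az) ** 2 <= 1.0
            take = inside & (e.priority > best)
            mu_seg = np.where(take, e.material.mu_eff_mm_inv, mu_seg)
            y_seg = np.where(take, e.material.scatter_yield * e.material.mu_eff_mm_inv, y_seg)
            best = np.where(take, e.priority, best)
        seg_len = np.where(live, dt, 0.0) * ray_len.ravel()
        od += mu_seg * seg_len
        ydepth += y_seg * seg_len
    return od.reshape(shape), ydepth.reshape(shape)


def project_primary(
    phantom: PhantomSpec,
    geom: AcquisitionGeometry,
    incident_mask: np.ndarray | None = None,
) -> ProjectionImage:
    """Analytic cone-beam primary projection (Beer-Lambert).

    Each detector pixel gets ``incident * exp(-sum mu_i * L_i)`` with exact
    ray-ellipsoid chord lengths.  Rays missing all ellipsoids arrive
    unattenuated.  ``incident_mask`` (e.g. the projected plate pattern)
    multiplies the incident fluence; absent means uniform incident 1.
    """
    od, _ = _path_integrals(phantom, geom)
    img = np.exp(-od)
    if incident_mask is not None:
        incident_mask = np.asarray(incident_mask, dtype=float)
        if incident_mask.shape != img.shape:
            raise ValueError("incident_mask shape must match the detector grid")
        img = incident_mask * img
    return ProjectionImage(img, geom.pixel_mm, role="primary_gt")


def scatter_source(
    phantom: PhantomSpec,
    geom: AcquisitionGeometry,
    incident_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Scatter-yield-weighted attenuated fluence per pixel.

    q = incident * ybar * (1 - exp(-od)) where ybar is the attenuation-
    weighted mean scatter yield along the ray. Linear in the incident
    fluence, which is what makes the shadow scatter a scaled-down copy of
    the full-field scatter.
    """
    od, ydepth = _path_integrals(phantom, geom)
    with np.errstate(invalid="ignore", divide="ignore"):
        ybar = np.where(od > 0, ydepth / np.where(od > 0, od, 1.0), 0.0)
    q = ybar * (1.0 - np.exp(-od))
    if incident_mask is not None:
        q = np.asarray(incident_mask, dtype=float) * q
    return q


def simulate_scatter(
    source: np.ndarray,
    params: ScatterModelParams,
    pixel_mm: float,
    mode: str = "nearest",
) -> ProjectionImage:
    """Convolve the scatter source with a broad normalized Gaussian kernel.

    Raises if the kernel breadth violates the low-frequency contract
    (sigma must exceed two pixels).
    """
    if params.kernel_sigma_mm <= 2.0 * pixel_mm:
        raise ValueError("kernel_sigma_mm must exceed 2 pixels: scatter is low-frequency")
    sigma_px = params.kernel_sigma_mm / pixel_mm
    sc = params.amplitude * ndimage.gaussian_filter(np.asarray(source, float), sigma_px, mode=mode)
    return ProjectionImage(sc, pixel_mm, role="scatter_gt")


def add_poisson_noise(
    img: np.ndarray,
    photons: float,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Replace each pixel by Poisson(photons * value) / photons.

    ``photons`` is the expected count at intensity 1.0; ``photons=0`` is the
    identity (noiseless).  Deterministic for a given seed/generator.
    """
    img = np.asarray(img, dtype=float)
    if np.any(img < 0):
        raise ValueError("Poisson noise requires a nonnegative image")
    if photons < 0:
        raise ValueError("photons must be nonnegative")
    if photons == 0:
        return img.copy()
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    return gen.poisson(photons * img).astype(float) / photons


def simulate_acquisition(
    phantom: PhantomSpec,
    geom: AcquisitionGeometry,
    bs: BeamStopperSpec | None,
    params: ScatterModelParams,
    seed: int | None = None,
    mask_offset_mm: tuple[float, float] = (0.0, 0.0),
    penumbra: bool = False,
) -> AcquisitionSet:
    """Simulate the paired acquisition.

    Without a plate: ``full_field = primary + scatter`` exactly (noiseless).
    With a plate the projected pattern multiplies the incident fluence
    BEFORE attenuation and scatter generation, so shadow pixels of the
    obstructed projection receive no primary at all (opaque default) and the
    reduced scatter field integrates to roughly the plate's open-area
    fraction of the full-field scatter.  Poisson noise, if requested, is
    applied last.
    """
    primary = project_primary(phantom, geom)
    q_full = scatter_source(phantom, geom)
    scatter = simulate_scatter(q_full, params, geom.pixel_mm)
    ff = primary.data + scatter.data
    rng = np.random.default_rng(seed)

    bs_proj = reduced = mask = None
    if bs is not None:
        mask = project_bs_mask(geom, bs, offset_mm=mask_offset_mm, penumbra=penumbra)
        reduced_sc = simulate_scatter(mask * q_full, params, geom.pixel_mm)
        bs_img = mask * primary.data + reduced_sc.data
        if params.noise_photons > 0:
            bs_img = add_poisson_noise(bs_img, params.noise_photons, rng)
        bs_proj = ProjectionImage(bs_img, geom.pixel_mm, role="bs")
        reduced = ProjectionImage(reduced_sc.data, geom.pixel_mm, role="scatter_gt")

    if params.noise_photons > 0:
        ff = add_poisson_noise(ff, params.noise_photons, rng)

    return AcquisitionSet(
        full_field=ProjectionImage(ff, geom.pixel_mm, role="full_field"),
        primary_gt=primary,
        scatter_gt=scatter,
        bs_projection=bs_proj,
        scatter_reduced_gt=reduced,
        bs_mask=mask,
    )
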