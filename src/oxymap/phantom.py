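"""Synthetic ground-truth objects: tumor pO2 phantoms and stained-tissue rasters.

The phantoms stand in for the imaged tumor volume: a circular tumor with a
hypoxic (low-pO2) core and a better-oxygenated rim, plus a spin-probe density
map, on a physical grid matching the imager's spatial field of view.  Control
tumors in this model sit near 15 torr mean pO2 with roughly half the pixels at
or below the 10-torr hypoxia threshold, and the generator targets a requested
hypoxic fraction by bisecting the core oxygen level.

Tissue rasters emulate Power-Doppler frames (red = flowing blood),
pimonidazole immunofluorescence (green = hypoxia marker) and endothelial
stains (dark = vessel), with *exact* known class-pixel counts so the
downstream fraction quantifiers can be verified to the single pixel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "OxygenPhantom",
    "TissueImage",
    "CLASS_CODES",
    "PALETTE",
    "make_tumor_phantom",
    "make_uniform_phantom",
    "make_flow_image",
    "make_ihc_image",
    "make_vessel_image",
]

#: class_truth codes
CLASS_CODES = {"background": 0, "flow": 1, "positive": 2, "vessel": 3}

#: fixture palette (8-bit RGB)
PALETTE = {
    "tissue": (180, 170, 170),
    "flow": (255, 0, 0),
    "positive": (0, 255, 0),
    "vessel": (30, 30, 30),
}


@dataclass(frozen=True)
class OxygenPhantom:
    """Ground-truth 2-D oxygen object.

    po2_grid : torr, >= 0 everywhere.
    density_grid : spin-probe concentration (arbitrary units >= 0), zero
        outside the support.
    tumor_mask : boolean tumor region.
    pixel_size : cm per pixel; ``fov = width * pixel_size``.
    """

    po2_grid: np.ndarray
    density_grid: np.ndarray
    tumor_mask: np.ndarray
    pixel_size: float
    seed: Optional[int] = None

    def __post_init__(self):
        po2 = np.asarray(self.po2_grid, dtype=float)
        den = np.asarray(self.density_grid, dtype=float)
        msk = np.asarray(self.tumor_mask, dtype=bool)
        if not (po2.shape == den.shape == msk.shape) or po2.ndim != 2:
            raise ValueError("phantom grids must be 2-D and share one shape")
        if np.any(po2 < 0):
            raise ValueError("pO2 must be non-negative")
        if np.any(den < 0):
            raise ValueError("density must be non-negative")
        object.__setattr__(self, "po2_grid", po2)
        object.__setattr__(self, "density_grid", den)
        object.__setattr__(self, "tumor_mask", msk)

    @property
    def shape(self):
        return self.po2_grid.shape

    @property
    def fov(self) -> float:
        """Physical extent in cm (square grids)."""
        return self.shape[1] * self.pixel_size

    def hypoxic_fraction(self, threshold: float = 10.0) -> float:
        """Brute-force hypoxic fraction: tumor pixels with pO2 <= threshold."""
        inside = self.po2_grid[self.tumor_mask]
        if inside.size == 0:
            raise ValueError("empty tumor mask")
        return float(np.count_nonzero(inside <= threshold) / inside.size)

    def mean_po2(self) -> float:
        return float(self.po2_grid[self.tumor_mask].mean())


@dataclass(frozen=True)
class TissueImage:
    """8-bit RGB raster with a tumor ROI and optional per-pixel class truth."""

    rgb: np.ndarray
    roi_mask: Optional[np.ndarray] = None
    class_truth: Optional[np.ndarray] = None
    seed: Optional[int] = None

    def __post_init__(self):
        rgb = np.asarray(self.rgb, dtype=np.uint8)
        if rgb.ndim != 3 or rgb.shape[2] != 3:
            raise ValueError("rgb must be (H, W, 3)")
        object.__setattr__(self, "rgb", rgb)
        if self.roi_mask is not None:
            roi = np.asarray(self.roi_mask, dtype=bool)
            if roi.shape != rgb.shape[:2]:
                raise ValueError("roi_mask shape must match rgb")
            object.__setattr__(self, "roi_mask", roi)
        if self.class_truth is not None:
            ct = np.asarray(self.class_truth, dtype=np.uint8)
            if ct.shape != rgb.shape[:2]:
                raise ValueError("class_truth shape must match rgb")
            object.__setattr__(self, "class_truth", ct)

    @property
    def shape(self):
        return self.rgb.shape[:2]


def _disc_mask(width: int, radius_px: float) -> np.ndarray:
    c = (width - 1) / 2.0
    yy, xx = np.mgrid[0:width, 0:width]
    return (xx - c) ** 2 + (yy - c) ** 2 <= radius_px**2


def make_tumor_phantom(
    width: int,
    mean_po2: float = 15.0,
    hypoxic_target: float = 0.50,
    core_radius: float = 0.6,
    noise_sd: float = 3.0,
    seed: int = 0,
    fov: float = 4.24,
    tumor_radius: float = 0.40,
    po2_max: float = 100.0,
    hf_threshold: float = 10.0,
    tol: float = 0.05,
) -> OxygenPhantom:
    """Circular tumor phantom with a targeted hypoxic fraction.

    The tumor is a disc of radius ``tumor_radius * width`` pixels with a
    two-level radial pO2 profile (low core, higher rim) plus seeded Gaussian
    spatial noise clipped at 0 torr.  The rim level is chosen so the
    *noiseless* profile has tumor-mean ``mean_po2``; the core level is then
    bisected until the realized hypoxic fraction (pixels <= ``hf_threshold``
    torr inside the tumor, counted on the final noisy grid) is within
    ``tol`` of ``hypoxic_target``.  The core is widened automatically when
    the requested fraction exceeds the requested core's area share.

    Defaults reproduce an untreated control tumor: mean pO2 15 torr, HF10
    0.5, 3-torr spatial heterogeneity, 4.24 cm field of view.

    Raises
    ------
    ValueError
        If the target is infeasible: with hypoxic pixels at <= ``hf_threshold``
        torr and the rest capped at ``po2_max`` torr, the largest reachable
        hypoxic fraction at the requested mean is
        ``(po2_max - mean_po2) / (po2_max - hf_threshold)``.
    """
    if width < 16:
        raise ValueError("width must be >= 16 pixels")
    if not 0.0 <= hypoxic_target <= 1.0:
        raise ValueError("hypoxic_target must be in [0, 1]")
    if mean_po2 < 0:
        raise ValueError("mean_po2 must be >= 0")
    hf_max = max(0.0, (po2_max - mean_po2) / (po2_max - hf_threshold))
    if hypoxic_target > min(1.0, hf_max) + 1e-12:
        raise ValueError(
            f"hypoxic_target {hypoxic_target} is unreachable with mean_po2 "
            f"{mean_po2} torr (max reachable ~{hf_max:.2f} with pO2 capped at {po2_max} torr)"
        )

    rng = np.random.default_rng(seed)
    pixel_size = fov / width
    r_tumor = tumor_radius * width
    tumor = _disc_mask(width, r_tumor)
    n_tumor = int(tumor.sum())
    noise = rng.normal(0.0, noise_sd, size=(width, width)) if noise_sd > 0 else np.zeros((width, width))

    if hypoxic_target == 0.0:
        po2 = np.clip(mean_po2 + noise, 0.0, None)
        po2[~tumor] = np.clip(mean_po2 + noise[~tumor], 0.0, None)
        density = np.where(tumor, 1.0, 0.0)
        return OxygenPhantom(po2, density, tumor, pixel_size, seed)

    # core must be able to hold the requested fraction; widen it if needed
    area_frac = min(core_radius**2, 0.92)
    if area_frac < hypoxic_target + 0.08:
        area_frac = min(hypoxic_target + 0.08, 0.92)
    core = _disc_mask(width, np.sqrt(area_frac) * r_tumor) & tumor
    n_core = int(core.sum())
    n_rim = n_tumor - n_core

    def realize(core_level: float) -> np.ndarray:
        if n_rim > 0:
            rim_level = (mean_po2 * n_tumor - core_level * n_core) / n_rim
            rim_level = min(max(rim_level, 0.0), po2_max)
        else:
            rim_level = core_level
        grid = np.full((width, width), mean_po2, dtype=float)
        grid[tumor] = rim_level
        grid[core] = core_level
        return np.clip(grid + noise, 0.0, None)

    def hf_of(core_level: float) -> float:
        grid = realize(core_level)
        return float(np.count_nonzero(grid[tumor] <= hf_threshold) / n_tumor)

    # HF decreases as the core level rises; coarse scan then bisection.
    # Cap the scan where the rim level would fall to the hypoxia threshold
    # (beyond that the mean constraint forces the rim itself hypoxic).
    lo, hi = 0.0, max(3.0 * hf_threshold, mean_po2 + 3.0 * noise_sd)
    if n_rim > 0 and n_core > 0:
        c_cap = (mean_po2 * n_tumor - (hf_threshold + 2.0) * n_rim) / n_core
        if c_cap > lo:
            hi = min(hi, c_cap)
    scan = np.linspace(lo, hi, 25)
    hfs = np.array([hf_of(c) for c in scan])
    best = int(np.argmin(np.abs(hfs - hypoxic_target)))
    c_star, hf_star = float(scan[best]), float(hfs[best])
    lo_b = float(scan[max(best - 1, 0)])
    hi_b = float(scan[min(best + 1, scan.size - 1)])
    for _ in range(50):
        if abs(hf_star - hypoxic_target) <= 0.5 * tol:
            break
        mid = 0.5 * (lo_b + hi_b)
        hf_mid = hf_of(mid)
        if abs(hf_mid - hypoxic_target) < abs(hf_star - hypoxic_target):
            c_star, hf_star = mid, hf_mid
        if hf_mid > hypoxic_target:  # too hypoxic -> raise core level
            lo_b = mid
        else:
            hi_b = mid
    if abs(hf_star - hypoxic_target) > tol:
        raise ValueError(
            f"could not realize hypoxic fraction {hypoxic_target} at mean_po2 "
            f"{mean_po2} torr (best {hf_star:.3f})"
        )
    po2 = realize(c_star)
    density = np.where(tumor, 1.0, 0.0)
    return OxygenPhantom(po2, density, tumor, pixel_size, seed)


def make_uniform_phantom(width: int, po2: float = 20.0, fov: float = 4.24,
                         tumor_radius: float = 0.40) -> OxygenPhantom:
    """Disc of uniform pO2 and uniform density — the basic round-trip object."""
    tumor = _disc_mask(width, tumor_radius * width)
    grid = np.full((width, width), float(po2))
    density = np.where(tumor, 1.0, 0.0)
    return OxygenPhantom(grid, density, tumor, fov / width, None)


def _paint_class_image(width, fraction, class_name, pattern, seed, roi_radius):
    """Common painter: exactly round(fraction * n_roi) pixels of one class."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"class fraction must be in [0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    roi = _disc_mask(width, roi_radius * width)
    roi_idx = np.flatnonzero(roi.ravel())
    n_roi = roi_idx.size
    n_class = int(round(fraction * n_roi))

    if pattern == "homogeneous" or n_class == 0:
        chosen = rng.choice(roi_idx, size=n_class, replace=False)
    elif pattern == "heterogeneous":
        # seeded cluster centers; take the n_class ROI pixels nearest any
        # center (jittered), which clusters labels while keeping the count exact
        n_centers = int(rng.integers(3, 7))
        centers = rng.choice(roi_idx, size=n_centers, replace=False)
        yy, xx = np.divmod(roi_idx, width)
        cy, cx = np.divmod(centers, width)
        d2 = ((yy[:, None] - cy[None, :]) ** 2 + (xx[:, None] - cx[None, :]) ** 2).min(axis=1)
        score = np.sqrt(d2) + rng.normal(0.0, 0.02 * width, size=n_roi)
        chosen = roi_idx[np.argsort(score, kind="stable")[:n_class]]
    else:
        raise ValueError(f"unknown pattern {pattern!r}")

    rgb = np.empty((width, width, 3), dtype=np.uint8)
    rgb[...] = PALETTE["tissue"]
    truth = np.full((width, width), CLASS_CODES["background"], dtype=np.uint8)
    flat_truth = truth.ravel()
    flat_truth[chosen] = CLASS_CODES[class_name]
    truth = flat_truth.reshape(width, width)
    rgb[truth == CLASS_CODES[class_name]] = PALETTE[class_name]
    return TissueImage(rgb=rgb, roi_mask=roi, class_truth=truth, seed=seed)


def make_flow_image(width: int, flow_fraction: float, seed: int = 0,
                    roi_radius: float = 0.45) -> TissueImage:
    """Power-Doppler-style frame: saturated-red flow pixels in a tumor ROI.

    Exactly ``round(flow_fraction * n_roi)`` pixels are painted in the flow
    class; the remainder is neutral tissue.  ``class_truth`` carries the
    ground truth used by exactness tests.
    """
    return _paint_class_image(width, flow_fraction, "flow", "homogeneous", seed, roi_radius)


def make_ihc_image(width: int, positive_fraction: float, pattern: str = "homogeneous",
                   seed: int = 0, roi_radius: float = 0.45) -> TissueImage:
    """Pimonidazole-style section: green hypoxia-positive pixels in the ROI.

    ``pattern="homogeneous"`` scatters positives uniformly at random;
    ``pattern="heterogeneous"`` places the same exact count in seeded
    clusters, emulating the patchier hypoxia seen after treatment.
    """
    return _paint_class_image(width, positive_fraction, "positive", pattern, seed, roi_radius)


def make_vessel_image(width: int, vessel_fraction: float, seed: int = 0,
                      roi_radius: float = 0.45) -> TissueImage:
    """Endothelium-stain-style section: dark vessel pixels in the ROI."""
    return _paint_class_image(width, vessel_fraction, "vessel", "homogeneous", seed, roi_radius)
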