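"""Oxygen maps and hypoxia statistics from a reconstructed spectral cube.

Each reconstructed pixel carries a first-derivative EPR spectrum; its
peak-to-peak linewidth is converted to pO2 through the probe calibration.
The region of interest is the set of pixels whose signal amplitude clears a
configurable fraction of the map maximum (probe-containing tissue); summary
statistics — mean and median pO2, a pO2 histogram, and the hypoxic fraction
HF10 (pixels at or below 10 torr, boundary inclusive) — are computed over
that region only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .recon import SpectralImageCube
from .spectral import CalibrationCurve, Spectrum, estimate_linewidth_pp, po2_from_linewidth

__all__ = [
    "OxygenMap",
    "MapStats",
    "DEFAULT_BIN_EDGES",
    "linewidth_map",
    "oxygen_map",
    "hf10",
    "map_stats",
]

#: default histogram bins: 0-100 torr in 5-torr steps
DEFAULT_BIN_EDGES = tuple(float(x) for x in range(0, 105, 5))


@dataclass(frozen=True)
class OxygenMap:
    """Per-pixel pO2 (torr) with signal amplitude and validity mask.

    ``po2`` is defined (and >= 0) wherever ``valid_mask`` is set;
    ``clamp_flags`` marks pixels whose linewidth fell below the calibration
    intercept and was clamped to 0 torr.  torr and mmHg are treated as the
    same unit.
    """

    po2: np.ndarray
    amplitude: np.ndarray
    valid_mask: np.ndarray
    pixel_size: float
    clamp_flags: np.ndarray

    def __post_init__(self):
        shapes = {np.asarray(a).shape for a in (self.po2, self.amplitude, self.valid_mask, self.clamp_flags)}
        if len(shapes) != 1:
            raise ValueError("all map grids must share one shape")
        if np.any(np.asarray(self.po2)[np.asarray(self.valid_mask, bool)] < 0):
            raise ValueError("valid pO2 must be non-negative")

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(self.valid_mask))


@dataclass(frozen=True)
class MapStats:
    """Summary statistics of an oxygen map over its valid region."""

    mean_po2: float
    median_po2: float
    hf10: float
    histogram: np.ndarray
    bin_edges: np.ndarray
    n_valid: int


def linewidth_map(cube: SpectralImageCube, bin_factor: int = 1, smooth_sigma_g: float = 0.0,
                  search_halfwidth_g: Optional[float] = None):
    """Estimate the peak-to-peak linewidth of every pixel spectrum.

    ``bin_factor`` block-averages the cube spatially first (oxygen maps are
    conventionally reported on coarser pixels than the reconstruction grid —
    about 2 x 2 mm here — which averages down reconstruction noise);
    ``smooth_sigma_g`` applies a Gaussian smoothing of that width (gauss)
    along the spectral axis before peak picking, the digital analogue of the
    spectrometer's output filter.  ``search_halfwidth_g`` restricts the
    extrema search to the admissible range around the center field (the
    sweep is centered on the probe's line); pass roughly the largest
    calibrated linewidth.  All three default off.

    Returns (linewidth grid [G], amplitude grid, flag grid) at the binned
    size.  A pixel is flagged when estimation fails outright (flat
    spectrum), an extremum sits on the sweep boundary, or the amplitude is
    at the pixel's own noise floor — in all three cases the linewidth would
    be unreliable.
    """
    values = cube.values
    if bin_factor > 1:
        n = values.shape[0] // bin_factor
        m = values.shape[1] // bin_factor
        values = values[: n * bin_factor, : m * bin_factor]
        values = values.reshape(n, bin_factor, m, bin_factor, -1).mean(axis=(1, 3))
    if smooth_sigma_g > 0:
        dv = cube.fov_spectral / cube.values.shape[2]
        values = gaussian_filter1d(values, smooth_sigma_g / dv, axis=2, mode="nearest")
    ny, nx, _ = values.shape
    axis = cube.spectral_axis
    lw = np.full((ny, nx), np.nan)
    amp = np.zeros((ny, nx))
    flagged = np.zeros((ny, nx), dtype=bool)
    for iy in range(ny):
        for ix in range(nx):
            est = estimate_linewidth_pp(
                Spectrum(field_axis=axis, intensity=values[iy, ix]),
                center=cube.center_field if search_halfwidth_g else None,
                search_halfwidth=search_halfwidth_g,
            )
            if not est.ok or est.flags:
                flagged[iy, ix] = True
            if est.ok:
                lw[iy, ix] = est.lw_pp
                amp[iy, ix] = est.amplitude
    return lw, amp, flagged


def oxygen_map(lw_grid, amp_grid, flag_grid, curve: CalibrationCurve,
               mask_rule: float = 0.15, pixel_size: float = 1.0) -> OxygenMap:
    """Convert a linewidth grid to an oxygen map through the calibration.

    ``mask_rule`` is the validity threshold as a fraction of the maximum
    amplitude; pixels below it, or flagged by the linewidth estimator, are
    excluded from the valid mask.  Sub-intercept linewidths clamp to 0 torr
    and are recorded in ``clamp_flags``.

    Raises ``ValueError`` when no pixel survives (no probe signal).
    """
    lw_grid = np.asarray(lw_grid, dtype=float)
    amp_grid = np.asarray(amp_grid, dtype=float)
    flag_grid = np.asarray(flag_grid, dtype=bool)
    if not (lw_grid.shape == amp_grid.shape == flag_grid.shape):
        raise ValueError("linewidth, amplitude and flag grids must share one shape")
    defined = ~flag_grid & np.isfinite(lw_grid) & (lw_grid > 0)
    amp_max = amp_grid[defined].max() if np.any(defined) else 0.0
    valid = defined & (amp_grid >= mask_rule * amp_max)
    if not np.any(valid):
        raise ValueError("empty valid mask: no probe signal above the amplitude threshold")
    po2 = np.zeros_like(lw_grid)
    clamped = np.zeros_like(flag_grid)
    vals, cl = po2_from_linewidth(curve, lw_grid[valid])
    po2[valid] = vals
    clamped[valid] = cl
    return OxygenMap(po2=po2, amplitude=amp_grid, valid_mask=valid,
                     pixel_size=pixel_size, clamp_flags=clamped)


def hf10(omap: OxygenMap, threshold: float = 10.0) -> float:
    """Hypoxic fraction: valid pixels with pO2 <= threshold (inclusive) / all valid."""
    vals = omap.po2[omap.valid_mask]
    if vals.size == 0:
        raise ValueError("no valid pixels")
    return float(np.count_nonzero(vals <= threshold) / vals.size)


def map_stats(omap: OxygenMap, bin_edges=DEFAULT_BIN_EDGES, hf_threshold: float = 10.0) -> MapStats:
    """Mean/median pO2, HF10 and a histogram over the valid region.

    Histogram bins are left-closed right-open with the final bin closed
    (numpy convention); counts sum to ``n_valid`` provided the edges span
    the data.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing with >= 2 values")
    vals = omap.po2[omap.valid_mask]
    if vals.size == 0:
        raise ValueError("no valid pixels")
    counts, _ = np.histogram(np.clip(vals, edges[0], edges[-1]), bins=edges)
    return MapStats(
        mean_po2=float(vals.mean()),
        median_po2=float(np.median(vals)),
        hf10=hf10(omap, hf_threshold),
        histogram=counts,
        bin_edges=edges,
        n_valid=int(vals.size),
    )
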