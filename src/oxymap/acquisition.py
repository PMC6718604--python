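"""Spectral-spatial EPR acquisition: projection scheme and forward model.

Spectral-spatial imaging treats the EPR field axis as an extra object
dimension.  The object here is h(x, y, B): spin density over two spatial
coordinates, each position carrying one resonance line whose width encodes
local pO2.  A field sweep under an in-plane gradient G applied along the
direction theta mixes spatial and spectral information: every pixel's line is
displaced by G * p, with p the pixel's position projected onto theta.  In
normalized coordinates (spatial axis scaled by the spatial FOV, spectral axis
by the spectral FOV) such a sweep is a parallel-beam projection of the
(position, field) plane at the *pseudo-angle*

    alpha = arctan(G * fov_spatial / fov_spectral),

so a finite maximum gradient leaves a "missing cone" of pseudo-angles beyond
alpha_max = arctan(g_max * fov_spatial / fov_spectral).  Each projection's
sweep width grows as fov_spectral / cos(alpha) so that no in-support pixel's
line is displaced outside the sweep.

The default scheme mirrors an L-band in-vivo protocol: 31 spatial angles x 14
pseudo-angles = 434 projections, 3 G/cm maximum gradient, 4.24 cm spatial and
5 G spectral field of view, 512 points per sweep, 390.95 G center field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .phantom import OxygenPhantom
from .spectral import _GAMMA_PER_LWPP, CalibrationCurve, _dlorentz

__all__ = [
    "Projection",
    "AcquisitionScheme",
    "ProjectionSet",
    "DEFAULT_SCHEME_PARAMS",
    "build_scheme",
    "default_scheme",
    "forward_project",
    "projection_masses",
]

#: L-band in-vivo protocol defaults (31 x 14 = 434 projections)
DEFAULT_SCHEME_PARAMS = dict(
    n_spatial=31,
    n_spectral=14,
    g_max=3.0,          # G/cm
    fov_spatial=4.24,   # cm
    fov_spectral=5.0,   # G
    n_points=512,
    center_field=390.95,  # G
)


@dataclass(frozen=True)
class Projection:
    """One sweep: spatial angle theta, pseudo-angle alpha, gradient, sweep width."""

    theta: float        # rad, in [0, pi)
    alpha: float        # rad, |alpha| <= alpha_max
    gradient: float     # G/cm
    sweep_width: float  # G


@dataclass(frozen=True)
class AcquisitionScheme:
    n_spatial: int
    n_spectral: int
    g_max: float
    fov_spatial: float
    fov_spectral: float
    n_points: int
    center_field: float
    projections: tuple = field(default_factory=tuple)

    @property
    def alpha_max(self) -> float:
        return math.atan(self.g_max * self.fov_spatial / self.fov_spectral)

    @property
    def n_projections(self) -> int:
        return len(self.projections)

    @property
    def thetas(self) -> np.ndarray:
        """Distinct spatial angles, ascending (spatial-major ordering)."""
        return np.array([self.projections[i * self.n_spectral].theta for i in range(self.n_spatial)])

    @property
    def alphas(self) -> np.ndarray:
        """Distinct pseudo-angles, ascending."""
        return np.array([p.alpha for p in self.projections[: self.n_spectral]])

    def field_axis(self, k: int) -> np.ndarray:
        """Swept-field axis (gauss) of projection ``k``."""
        sw = self.projections[k].sweep_width
        return np.linspace(self.center_field - sw / 2, self.center_field + sw / 2, self.n_points)


def build_scheme(
    n_spatial: int,
    n_spectral: int,
    g_max: float,
    fov_spatial: float,
    fov_spectral: float,
    n_points: int,
    center_field: float,
) -> AcquisitionScheme:
    """Cross product of uniform spatial angles and uniform pseudo-angles.

    Spatial angles are uniform on [0, pi); pseudo-angles are ``n_spectral``
    values uniform on [-alpha_max, +alpha_max] with the endpoints included
    (a single value sits at alpha = 0).  Projections are ordered
    spatial-major with alpha ascending, ``gradient = tan(alpha) *
    fov_spectral / fov_spatial`` and ``sweep_width = fov_spectral /
    cos(alpha)``.
    """
    if n_spatial < 1 or n_spectral < 1:
        raise ValueError("angle counts must be >= 1")
    if g_max <= 0 or fov_spatial <= 0 or fov_spectral <= 0 or n_points <= 0:
        raise ValueError("g_max, FOVs and n_points must be positive")
    alpha_max = math.atan(g_max * fov_spatial / fov_spectral)
    thetas = np.arange(n_spatial) * math.pi / n_spatial
    if n_spectral == 1:
        alphas = np.array([0.0])
    else:
        alphas = np.linspace(-alpha_max, alpha_max, n_spectral)
    projections = []
    for th in thetas:
        for al in alphas:
            grad = math.tan(al) * fov_spectral / fov_spatial
            projections.append(
                Projection(theta=float(th), alpha=float(al), gradient=grad,
                           sweep_width=fov_spectral / math.cos(al))
            )
    return AcquisitionScheme(
        n_spatial=n_spatial,
        n_spectral=n_spectral,
        g_max=g_max,
        fov_spatial=fov_spatial,
        fov_spectral=fov_spectral,
        n_points=n_points,
        center_field=center_field,
        projections=tuple(projections),
    )


def default_scheme(**overrides) -> AcquisitionScheme:
    """The 434-projection L-band default scheme (see module docstring)."""
    params = dict(DEFAULT_SCHEME_PARAMS)
    params.update(overrides)
    return build_scheme(**params)


@dataclass(frozen=True)
class ProjectionSet:
    """Acquired/simulated projection spectra, one row per projection."""

    scheme: AcquisitionScheme
    spectra: np.ndarray  # (n_projections, n_points)
    noise_sd: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self):
        spectra = np.asarray(self.spectra, dtype=float)
        if spectra.shape != (self.scheme.n_projections, self.scheme.n_points):
            raise ValueError(
                f"spectra shape {spectra.shape} does not match scheme "
                f"({self.scheme.n_projections} x {self.scheme.n_points})"
            )
        object.__setattr__(self, "spectra", spectra)

    @property
    def n_projections(self) -> int:
        return self.scheme.n_projections


def _pixel_coordinates(phantom: OxygenPhantom):
    """Physical pixel-center coordinates (cm), origin at the grid center.

    x runs along columns, y along rows (row index increasing downward).
    """
    ny, nx = phantom.shape
    px = phantom.pixel_size
    x = (np.arange(nx) - (nx - 1) / 2.0) * px
    y = (np.arange(ny) - (ny - 1) / 2.0) * px
    return np.meshgrid(x, y)


def _windowed_double_integral(rows: np.ndarray, step: float) -> np.ndarray:
    """Double integral of derivative rows over their window: the absorption area."""
    rows = np.atleast_2d(rows)
    return np.sum(np.cumsum(rows, axis=-1), axis=-1) * step * step




def projection_masses(ps: ProjectionSet) -> np.ndarray:
    """Absorption area (double integral) of every projection, in its own field units."""
    steps = np.array([p.sweep_width for p in ps.scheme.projections]) / (ps.scheme.n_points - 1)
    first = np.cumsum(ps.spectra, axis=1)
    return np.sum(first, axis=1) * steps * steps


def forward_project(
    phantom: OxygenPhantom,
    curve: CalibrationCurve,
    scheme: AcquisitionScheme,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> ProjectionSet:
    """Simulate the projection spectra of a phantom under the scheme.

    For every projection, every phantom pixel with non-zero density
    contributes one first-derivative Lorentzian line with

    * linewidth = ``curve.linewidth(pixel pO2)``,
    * field offset = ``gradient * (x cos(theta) + y sin(theta))``,
    * windowed mass (double integral over the sweep) exactly equal to the
      pixel density, so every sweep accounts each spin once.

    A truncated Lorentzian's absorption does not vanish at the sweep edges,
    so the raw double integral of a line over a finite window depends on
    where the window cuts its tails.  Each line therefore carries a small
    constant derivative offset — a linear absorption baseline, the
    forward-model analogue of the baseline correction applied before double
    integration in EPR quantitation — chosen so its windowed mass equals
    the pixel density exactly.  A constant neither moves the derivative
    extrema (the lineshape around them stays exactly Lorentzian) nor
    survives the reconstruction's ramp filter, which zeroes DC.

    Contributions are summed onto the sweep axis and seeded white Gaussian
    noise of standard deviation ``noise_sd`` is added.

    Raises
    ------
    ValueError
        If the phantom is wider than the scheme's spatial FOV, or if any
        occupied pixel's line center falls outside a projection's sweep
        (the error names the offending projection).
    """
    if phantom.fov > scheme.fov_spatial * (1 + 1e-9):
        raise ValueError(
            f"phantom FOV {phantom.fov:.3f} cm exceeds scheme spatial FOV "
            f"{scheme.fov_spatial:.3f} cm"
        )
    xx, yy = _pixel_coordinates(phantom)
    occupied = phantom.density_grid > 0
    dens = phantom.density_grid[occupied]
    px_x = xx[occupied]
    px_y = yy[occupied]
    lw = np.asarray(curve.linewidth(phantom.po2_grid[occupied]), dtype=float)
    gamma = _GAMMA_PER_LWPP * lw  # HWHM per pixel

    n_proj, n_pts = scheme.n_projections, scheme.n_points
    spectra = np.zeros((n_proj, n_pts))
    for k, proj in enumerate(scheme.projections):
        offsets = proj.gradient * (px_x * math.cos(proj.theta) + px_y * math.sin(proj.theta))
        half = proj.sweep_width / 2.0
        if np.any(np.abs(offsets) > half):
            raise ValueError(
                f"projection {k} (theta={proj.theta:.3f}, alpha={proj.alpha:.3f}): "
                "pixel line center falls outside the sweep window (sweep too narrow)"
            )
        step = proj.sweep_width / (n_pts - 1)
        axis = np.linspace(-half, half, n_pts)
        lines = _dlorentz(axis[None, :] - offsets[:, None], gamma[:, None])  # unit area
        masses = _windowed_double_integral(lines, step)
        # constant derivative offset = linear absorption baseline; fixes each
        # line's windowed mass at exactly 1 without moving its extrema
        dd_const = step * step * n_pts * (n_pts + 1) / 2.0
        baselines = (1.0 - masses) / dd_const
        spectra[k] = dens @ lines + float(dens @ baselines)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        spectra = spectra + rng.normal(0.0, noise_sd, size=spectra.shape)
    return ProjectionSet(scheme=scheme, spectra=spectra, noise_sd=noise_sd, seed=seed)
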