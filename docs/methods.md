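# Methods

`oxymap` simulates and analyzes spectral-spatial EPR oximetry of tumor
phantoms and quantifies treatment-response readouts from tissue images.
This note describes the models, the numerical choices behind them, and what
the synthetic data do and do not establish about real measurements.

## The physical model

### Oxygen and the nitroxide line

Dissolved molecular oxygen broadens a nitroxide spin probe's EPR line by
Heisenberg spin exchange. The broadening is homogeneous, so the single
resonance is modelled as a Lorentzian; continuous-wave EPR records its first
field derivative, whose extrema are separated by the peak-to-peak linewidth
`lw_pp = 2γ/√3` (γ the half-width at half maximum of the absorption). The
linewidth-pO2 relation is affine,

    lw_pp(pO2) = lw0 + m · pO2,     m > 0,

fitted by ordinary least squares to calibration points measured at known
oxygen fractions (0, 3, 21 % O2, converted to torr at one standard
atmosphere, 760 torr — the conversion pressure is a configurable argument).
The package ships a synthetic default calibration (`lw0 = 1.0` G,
`m = 0.01` G/torr) spanning a realistic nitroxide range over 0–160 torr;
real probes require their own measured points. Field-modulation broadening
is not modelled explicitly; it is treated as absorbed into the calibration
intercept, which is how an empirical calibration acquired on the same
instrument would behave.

### Spectral-spatial acquisition

The imaged object is `h(x, y, B)`: spin density over two spatial
coordinates, each position carrying one line whose width encodes local pO2.
A field sweep under an in-plane gradient `G` along direction θ displaces
every pixel's line by `G·(x cosθ + y sinθ)`. In normalized coordinates
(space scaled by the spatial FOV `L_x`, field by the spectral FOV `L_B`)
that sweep is a parallel-beam projection of the (position, field) plane at
the pseudo-angle `α = arctan(G·L_x/L_B)`. The gradient cap `g_max` limits
`|α| ≤ α_max = arctan(g_max·L_x/L_B)`; the default protocol
(31 spatial × 14 spectral angles = 434 projections, 3 G/cm, 4.24 cm / 5 G
FOVs, 512 points per sweep, 390.95 G center field) has `α_max = 68.5°`,
leaving a ±21.5° *missing cone* of pseudo-angles. Sweep widths grow as
`L_B/cos α` so no in-support line leaves its window; consequently all
projections share one normalized ray axis. Pseudo-angles are spaced
uniformly in α with both extremes included (an odd count places one sweep
at exactly zero gradient); spatial angles are uniform on [0, π).

### Forward model and mass convention

Each occupied pixel contributes an area-normalized derivative Lorentzian at
its displaced field position. A truncated Lorentzian's absorption does not
vanish at the sweep edges, so the raw double integral over a finite window
depends on where the tails are cut. Each line therefore carries a small
constant derivative offset — a linear absorption baseline, the
forward-model analogue of the baseline correction performed before double
integration in EPR quantitation — chosen so its windowed double integral
equals the pixel's density exactly. A constant moves neither the extrema
(the lineshape around them stays exactly Lorentzian) nor survives the
reconstruction's ramp filter. As a result every noiseless projection's
absorption mass equals the phantom's total spin count to machine precision,
and the forward operator is exactly linear in density. Noise is white
Gaussian, seeded, added per field sample.

## Reconstruction

Reconstruction follows the printed processing chain: 512-point sweeps are
block-averaged to 128 points (area preserving), projections are linearly
interpolated by a factor of 4 in each angular dimension, Ram-Lak
(|frequency| ramp) filtered with the cutoff at half Nyquist, and inverted by
filtered back-projection, two stages:

1. per spatial angle θ, the pseudo-angle fan — each sweep weighted by
   `1/cos α`, which converts it to the normalized-plane Radon transform —
   is inverted onto the (projected-position, field) plane;
2. per spectral slice, the θ-profiles form an ordinary sinogram inverted by
   parallel-beam FBP.

The θ interpolation wraps at π; the wrapped neighbor of the last spatial
angle is the first angle's fan with the pseudo-angle sign reversed (the
physically correct partner at θ+π). Because all projections share one
normalized ray axis, pointwise interpolation of sample columns interpolates
at fixed ray coordinate.

Numerical choices that matter:

- **Edge-continuation padding.** EPR lineshapes have long tails, so the
  sweep window truncates every projection; ramp-filtering truncated rows
  directly produces large low-frequency bowls across the reconstruction
  (the interior-tomography artifact), which dominate every pixel spectrum.
  Each row is extended by half its length per side — edge value held, then
  cosine-rolled to zero — before filtering, and back-projection samples the
  padded extent.
- **FFT upsampling (×4) of filtered rows** before linear-interpolation
  back-projection, keeping interpolation blur below the filter resolution.
- **Missing cone.** Default: the filtered extreme-α projections are
  replicated into the unacquired cone at the acquired spacing (the
  conventional choice). Configurable alternatives: `reproject` (one or more
  consistency passes that re-project the current plane estimate at the
  missing angles) and `zero` (leave the cone empty).
- **Normalization.** The cube is scaled so its total absorption mass equals
  the mean projection mass, making amplitude maps comparable across
  schemes.
- The second-stage cutoff can be set separately (`filter_cutoff_spatial`);
  by default it reuses the printed cutoff.

## Oxygen maps and statistics

Every pixel spectrum gets a peak-to-peak linewidth: global maximum and
minimum of the derivative curve (first occurrence on ties), each refined by
three-point parabolic interpolation. Optional robustness aids, all off by
default: restricting the extrema search to the admissible window around the
center field (the sweep is centered on the line by design), spatial
block-averaging to coarser map pixels (reported oxygen maps conventionally
use ~2×2 mm pixels), and Gaussian spectral smoothing emulating the
spectrometer output filter. Estimates are flagged when the spectrum is
flat, an extremum sits on the sweep boundary, the extrema violate the
derivative line's low-field-maximum/high-field-minimum order, or the
amplitude is at the pixel's noise floor (estimated robustly from the sweep
ends: the larger of an MAD-of-first-differences roughness measure and a
per-edge value spread).

The region of interest is the set of unflagged pixels whose amplitude
reaches `mask_rule` (default 15 %) of the map maximum — a proxy for
probe-containing tissue; the threshold is configurable because the in-vivo
"region of interest" is operator-defined. Statistics over that region:
mean and median pO2, a histogram (default 0–100 torr in 5-torr bins,
left-closed with the final bin closed), and the hypoxic fraction HF10 —
pixels with pO2 ≤ 10 torr (boundary inclusive) over all valid pixels.
Sub-intercept linewidths clamp to 0 torr and are flagged. torr and mmHg
are treated as the same unit.

## Synthetic data

The tumor phantom is a disc (radius 0.40 of the grid by default) with a
two-level radial pO2 profile — a hypoxic core and a better-oxygenated rim —
plus seeded Gaussian spatial noise (3 torr default) clipped at zero. The
rim level is set from the requested tumor mean (15 torr default, matching
untreated control tumors); the core level is then bisected (after a coarse
scan, ≤ 50 refinement steps) until the realized HF10 is within ±0.05 of the
request (0.50 default, also the control-tumor value). Requests are rejected
as infeasible when the mean cannot coexist with the hypoxic fraction under
a 100-torr ceiling. Spin-probe density is uniform inside the tumor and
zero outside — the simplest reading of an intratumoral injection; probe
spread into surrounding tissue and the depth-averaging of a surface-coil
acquisition are *not* modelled.

Tissue rasters paint exactly `round(fraction × ROI)` pixels of a saturated
class color (red flow, green hypoxia marker, dark vessels) in a circular
ROI on neutral tissue, either uniformly or in seeded clusters
(`heterogeneous`), so fraction quantifiers can be verified to the single
pixel. The classifier rules are tuned to this palette; real histology
requires recalibrated thresholds (and possibly color deconvolution, which
is out of scope).

## Known limitations

- **The missing cone bounds per-pixel accuracy.** With the default
  protocol's `α_max = 68.5°`, per-pixel pO2 on uniform phantoms has a
  median absolute error of roughly 4–5 torr (with a systematic radial
  pattern: interior broadened, rim narrowed), for every cone treatment we
  implemented. A control experiment with a complete simulated fan (|α| to
  88°) reaches ~0.5 torr through the identical chain, isolating the cone as
  the cause. Iterative or regularized reconstruction, which could do
  better, is deliberately out of scope.
- **Noise amplification.** Two ramp-filtered inversion stages amplify
  white projection noise strongly; at a projection signal-to-noise ratio of
  20 (peak of the strongest projection over the noise standard deviation),
  per-pixel spectral SNR is only a few units and peak picking is noise
  biased. Map-level statistics at that noise level are unreliable without
  aggressive spatial binning, which in turn dilutes HF10 across the
  core boundary. Quantitative per-pixel oximetry in this pipeline wants a
  projection SNR of roughly 100 or better.
- Passing tests on these phantoms demonstrate the correctness of the
  computations and the documented accuracy of the inversion under the
  stated geometry — not the fidelity of any real in-vivo map, which is
  additionally affected by probe pharmacokinetics, depth averaging, animal
  motion and operator ROI choices.

## Problem sizes used in the shipped checks

The end-to-end checks run the full 434-projection protocol with a 128³ cube
on 64×64 phantoms for the noiseless round trip, and a scaled 16×8-angle
scheme for the multi-seed hypoxic-fraction studies; tissue-image checks use
150–200-pixel rasters. These sizes were chosen so the whole suite documents
the pipeline's behavior at full protocol fidelity where it matters and at
reduced angular sampling where many replicates are needed.
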