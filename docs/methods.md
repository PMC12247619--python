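# Methods

## Steady-state signal models

Both line-scanning sequences are modelled at the level of longitudinal
steady state: a train of identical excitations every TR drives Mz to a fixed
point, and the transverse signal at the echo is the closed-form solution of
the Bloch equations with pure T1 recovery between pulses and exponential
transverse decay to TE. For the spin-echo (α-180) scheme the refocusing pulse
at TE/2 also rotates the longitudinal magnetisation, which is why the
refocusing angle β enters the recovery terms; at β = 0 (cos β = 1) the
expression collapses exactly onto the spoiled gradient-echo form, a property
the test suite asserts to machine precision. The closed form is additionally
cross-checked in the tests against an independent oracle that iterates the
two-interval Bloch recursion to convergence.

Assumptions: ideal spoiling (no transverse coherence survives a TR), ideal
hard pulses, a single tissue compartment, no B1 inhomogeneity, no inflow.
Slice profiles, off-resonance and SAR are out of scope.

**Relative tSNR.** Protocols are compared through
`S_steady × FOV_readout[m] / √BW[Hz]`: tSNR is assumed linear in SNR, voxel
volume varies only through the readout FOV (fixed matrix and slice), and
noise grows with the square root of the acquisition bandwidth. The output is
an arbitrary-unit figure of merit, exactly linear in FOV and ∝ BW^(−1/2);
only ratios between protocols evaluated with the same convention are
meaningful. Noise-source composition (thermal vs. physiological vs. residual
background) is deliberately not decomposed. The convention string is embedded
in the `optimize-fa` output so downstream users can see which scaling
produced the number.

**Relaxation defaults** (rat somatosensory cortex at high field): T1 =
2211 ms, T2 = 24 ms, T2\* = 20 ms. These are defaults of `SequenceParams`,
not constants.

**Flip-angle optimisation** is analytic where a closed form exists
(`arccos(−E1)` for SE with β = 180°, Ernst angle for GRE) and falls back to a
0.1°-grid search over (0°, 180°] otherwise; ties break toward the smaller
angle. The analytic optimum is TE-independent because the transverse decay
factorises out of the α-dependence.

## Block HRF and GLM

The kernel `g(t) = t⁴e^(−t)/(4⁴e^(−4))` peaks at 1 at t = 4 s; the response
to an L-second block is `HRF(t) = ∫₀^min(t,L) g(s) ds`, evaluated in closed
form through the regularised lower incomplete gamma function. The design
regressor samples this model at the series TR and is peak-normalised so a
GLM coefficient is the peak response height in the series' units.

**Per-epoch convolution (design choice).** The regressor is built by
convolving a single epoch's stimulus indicator with g over one epoch and
tiling it, rather than convolving the whole series. At a 20-s epoch the
response carry-over past the epoch boundary is below 0.4 % of peak; dropping
it makes every epoch's expected response identical and — more importantly —
leaves the 1-s pre-stimulation windows exactly at baseline, so the
percent-change baseline S0 is unbiased by the tail of the previous epoch and
noiseless simulations recover their ground-truth amplitude to numerical
precision. Full-series convolution with a 32-s kernel support remains
available (`per_epoch=False`) for paradigms whose epochs are short enough
for carry-over to matter scientifically.

The GLM design is intercept + linear drift + regressor, fitted per depth by
least squares; heavier trend removal belongs to the preprocessing stage
(cubic detrend), mirroring the processing order of the analysis chain. A
rank-deficient design raises an error naming the collinear column.

## Synthetic data generator

The generator emulates the study conditions of the modelled protocols:
40 depth bins × 50 µm spanning 0–2 mm of cortex (20 × 100 µm for the fast
spin-echo protocol), a 1 s pre / 4 s stim / 15 s post block repeated 32
times (6400 timepoints at TR 100 ms, 640 s), multiplicative BOLD responses
`baseline·(1 + amplitude/100·regressor)`, a slow additive polynomial drift,
and independent Gaussian noise per sample as a thermal-noise stand-in.
Optional sinusoids (~0.3 Hz "respiration", ~1 Hz "cardiac") are available as
physiological confound stand-ins but are off by default, since no noise
spectrum is available to calibrate them. Depth convention: bin i is centred
at (i + 0.5)·Δz, index 0 at the pial surface.

Amplitude profile presets: gradient-echo-like = surface-peaked 30 %
(draining-vein weighting), spin-echo-like = layer-4-peaked 10 % at 0.9 mm
with 0.4 mm Gaussian width. These defaults are documentation of typical
shapes, not biological claims. Preset noise levels are set to mean
whole-series tSNR targets of 15.3 (geline), 50.8 (seline) and 27.0
(seline-fast); because the evoked response and drift also contribute to the
whole-series SD, the measured tSNR of a preset run lands a few percent below
its thermal-noise target, which is the expected behaviour of this σ
convention. Drift coefficients are kept at order ≤ 3 so the cubic detrend
can remove the drift exactly — this makes detrending itself testable.

What the generator does **not** emulate: spatially correlated physiological
noise, motion, inflow/CSF partial volume, B1⁻ shading across depth,
k-space/readout physics. Pipeline recovery results on this synthetic data
therefore demonstrate correctness of the computation, not robustness to
those real-world confounds.

The 2D phantom is a unit-intensity strip of `round(width/pixel)` contiguous
phase-encode pixels (so its nominal width is an exact pixel multiple),
Gaussian-blurrable edges, and a uniform residual background at a stated
fraction of the in-strip intensity.

## Preprocessing numerics

- **Detrend**: least-squares polynomial fit on time normalised to [−1, 1]
  (numerically tame Vandermonde); residual orthogonal to the basis.
- **Bandpass**: Hamming-windowed linear-phase FIR (`scipy.signal.firwin`,
  order 4096 i.e. 4097 taps, 0.01–0.1 Hz), applied causally and re-aligned
  by a circular shift of order/2 samples — the constant group delay of a
  linear-phase FIR. Hamming is the conventional default of windowed-sinc
  design and is recorded in the report metadata. The circular shift wraps
  order/2 samples from the end of the record to the start; `validity_mask`
  marks the affected edge samples rather than silently trusting them.
- **Short records**: when the record is shorter than the requested order
  (e.g. 640 samples at TR 1000 ms), the order is capped at the largest even
  integer ≤ N/3 with a logged warning, preserving the passband while keeping
  the design well-posed; `cap_order=False` turns this into an error.
- **σ convention**: population SD (divide by N) for z-score and tSNR;
  the difference from the sample convention is < 0.1 % at these record
  lengths but the choice is fixed and documented.
- **tSNR** is always computed on the raw series, per depth, as mean over the
  SD of the *whole* time course — baseline windows are too short under a
  4 s-on / 16 s-off design to stand in for rest. A flag allows tSNR of the
  conditioned series instead.

## Depth-resolved metrics

- **Percent change** uses S0 = per-depth mean over the union of every
  epoch's pre-stimulation window across the whole series. The default map is
  computed on the demeaned/detrended/bandpassed series with the temporal
  mean restored (flag for the unfiltered variant); peak location is robust
  to the bandpass since the attenuation is depth-independent, while the
  reported **amplitude** comes from the GLM on the unfiltered
  (detrended-only) map so the passband cannot bias it.
- **Layer scheme** defaults (L1 0–0.15, L2/3 0.15–0.70, L4 0.70–1.10,
  L5 1.10–1.60, L6 1.60–2.00 mm) follow standard rat S1 histology ranges and
  are configuration, not constants. Laminar slope is the difference of the
  normalised profile between two layers' interval-midpoint depths (linear
  interpolation), in normalised units per layer step.
- **Peak detection** statistic is the per-depth temporal maximum of the
  epoch-averaged percent-change map (flag for a window mean); all ties break
  toward the shallower depth / earlier time.
- **FWHM** interpolates the half-maximum crossings walking outward from the
  global peak, so a multimodal profile reports the width of the lobe
  containing the global maximum.
- **Surface detection** uses a documented stand-in rule: first depth index
  (from the shallow end) reaching 50 % of the 95th-percentile robust
  maximum; both fraction and percentile are configurable.

## Problem sizes

Default simulations are single trials (40 × 6400 samples, ≈ 0.3 s per full
pipeline run); the seeded Monte-Carlo recovery check uses 20 such trials.
These sizes are chosen so ground-truth recovery statistics (peak layer,
amplitude within 10 %, tSNR within 5 %) are well-resolved while the whole
suite stays interactive.

## Known limitations

- The steady-state model ignores stimulated echoes and imperfect spoiling;
  at β far from 180° with short TR the true sequence deviates from the
  closed form.
- The relative-tSNR convention omits voxel count, coil sensitivity and TR;
  it reproduces between-protocol ratios only under the stated assumptions.
- The bandpass attenuates the block-response harmonics above 0.1 Hz, so
  epoch-average peak amplitudes from the filtered map are systematically
  below ground truth; use the GLM amplitude (default) when absolute percent
  change matters.
- Surface detection is a heuristic stand-in; real line profiles with bright
  CSF or vessels above the cortex may need a different rule.
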