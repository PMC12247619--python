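# lamline

Steady-state signal models, synthetic data generation and depth-resolved BOLD
analysis for **line-scanning laminar fMRI**.

Line-scanning fMRI turns off phase encoding and acquires a single k-space line
per repetition, trading a 2D image for a 1D profile across the cortical depth
at very high temporal resolution (TR of 100–1000 ms, 50–100 µm depth bins).
Two acquisition schemes are modelled: a gradient-echo variant (GELINE,
T2\*-weighted, sensitive to superficial draining veins) and a spin-echo
"α-180" variant (SELINE, T2-weighted, microvascular weighting), in which the
refocusing pulse is applied perpendicular to the excitation slice so the line
profile is selected without saturation pulses.

The package is for researchers designing or analysing such protocols: it
predicts steady-state signal and relative tSNR from sequence parameters,
generates seeded synthetic depth×time acquisitions with known ground truth,
and runs the full depth-resolved percent-change analysis.

## The models

**Steady state.** With `E1 = exp(−TR/T1)` and `E1′ = exp(−(TR−TE/2)/T1)`:

```
SE:   S(α,β) = sin α · [1 − cos β·E1 − (1 − cos β)·E1′] / (1 − cos α·cos β·E1) · e^(−TE/T2)
GRE:  S(θ)   = sin θ · (1 − E1) / (1 − cos θ·E1) · e^(−TE/T2*)
```

The signal-maximising excitation angles are `α* = arccos(−E1)` (SE, β = 180°)
and the Ernst angle `θ* = arccos(E1)` (GRE). A protocol's **relative tSNR** is
`S · FOV[m] / √BW[Hz]`, assuming tSNR linear in SNR, voxel size set by the
readout FOV and noise ∝ √bandwidth. **tSNR efficiency** is `tSNR / √(TR[s])`.

**Block HRF.** The response to an L-second stimulus block is the convolution
of the stimulus square wave with the gamma-variate kernel
`g(t) = t⁴e^(−t) / (4⁴e^(−4))` (peak 1 at t = 4 s), peak-normalised so a
fitted GLM amplitude reads directly as peak percent change.

**Analysis chain.** tSNR = per-depth mean / SD of the whole raw time course;
demean → cubic detrend → zero-phase FIR bandpass (0.01–0.1 Hz, order 4096,
Hamming, group delay compensated by circular shift); percent change
`(S − S0)/S0 × 100` with S0 from the 1-s pre-stimulation windows of all
epochs; epoch averaging; peak-layer detection against a configurable cortical
layer scheme; profile normalisation by max(mean + SD); FWHM and background
fraction (`N_bkg/S_roi × 100 %`) for 2D slice-profile quality.

## Worked example

```python
import lamline as L

se, ge = L.PROTOCOL_PRESETS["seline"], L.PROTOCOL_PRESETS["geline"]
print(L.predicted_relative_tsnr(se))   # 7.0421841271856525e-06
print(L.predicted_relative_tsnr(ge))   # 3.1694905727242907e-06
print(L.tsnr_ratio(se, ge))            # 2.221866248093189
print(L.optimal_flip_angle(L.PROTOCOL_PRESETS["seline-fast"]))  # 155.99553954297008
print(L.tsnr_efficiency(15.3, 100), L.tsnr_efficiency(27.0, 200))
# 48.382848200576205 60.37383539249432

rep = L.run_pipeline(L.RunConfig.from_preset("seline", seed=7))
print(round(rep["tsnr"]["mean"], 1))        # 37.2
print(rep["peak"])                          # peak 7.5 % at 0.875 mm -> layer L4
print(round(rep["amplitude_glm"]["peak_pct"], 2))  # 10.23  (ground truth: 10 %)
```

The spin-echo protocol (TR 1000 ms / TE 20 ms, 90°/180°, FOV 3.2 mm,
BW 5000 Hz) is predicted ~2.2× the relative tSNR of the gradient-echo one
(TR 100 ms / TE 12.5 ms, 50°, FOV 6.4 mm, BW 9014 Hz) — the SE signal per
voxel is larger and the readout bandwidth lower. The synthetic SELINE run
plants a 10 % layer-4-peaked response at 0.9 mm; the pipeline's GLM recovers
10.2 % in L4 (the epoch-average peak of 7.5 % is lower because the 0.01–0.1 Hz
bandpass attenuates harmonics of the 20-s block response).

The same is available from a shell:

```bash
lamline optimize-fa --preset seline-fast
lamline simulate --preset seline --seed 7 --out run.nii
lamline analyze --in run.nii --paradigm-config paradigm.json --out-dir out/
lamline profile-2d --synthetic --background-frac 0.05
lamline report --preset seline --seed 7 --out report.json
```

## Layout

- `lamline.sequences` — steady-state models, flip-angle optimisation, tSNR prediction
- `lamline.paradigm` — block paradigm, gamma block HRF, GLM amplitude
- `lamline.synthetic` — seeded generators for series, profiles and 2D phantoms
- `lamline.preprocess` — demean / detrend / zero-phase bandpass / z-score / tSNR
- `lamline.metrics` — percent change, epoch averaging, peak layer, slope, FWHM, background
- `lamline.pipeline`, `lamline.cli`, `lamline.io` — orchestration, CLI, NIfTI+sidecar/TSV/JSON I/O

See `docs/methods.md` for modelling assumptions, parameter defaults and
numerical choices.
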