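# Methods

This note records the models implemented by `hcpasl_lite`, the defaults
and why they were chosen, what the synthetic phantom does and does not
emulate, and the numerical choices that affect results.

## Acquisition model

All timing derives from one object, `AcquisitionProtocol`: label duration
τ = 1.5 s; PLDs 0.2–2.2 s repeated 6/6/6/10/15 times (86 ASL volumes);
60 slices in 6 contiguous SMS bands of 10; 59 ms readout per slice
excitation; TE 19 ms; two long-TR (8 s) proton-density calibration
images. Slice `s` has within-band position `p = s mod 10` and slice-timing
offset `δ(s) = p · 59 ms`. Bands are contiguous along Z with ascending
acquisition order within the band; the slice axis is always the third
voxel axis, 0-based. Volume ordering is control-then-label pairs grouped
by PLD; only the (PLD, label/control) annotation of each volume matters
downstream, not the ordering convention itself.

## Phantom

Geometry: nested tissue compartments **extruded along Z** (a CSF core
standing in for the ventricles, a WM annulus, a GM ribbon), with linear
partial-volume transitions about one voxel wide. Extrusion keeps slice
composition stationary along Z so that slice-wise statistics — the
empirical-gradient fit and the band discontinuity index — are driven by
the banding mechanisms, not by anatomy. This trades anatomical realism
for statistical interpretability, which is the phantom's purpose.

Signal model per volume, in acquisition order:

1. anatomy fields (M0t, T1t, PVs, aBV) are translated by the volume's
   motion vector (trilinear; motion is translation-only by design — enough
   to exercise motion-resolved correction without a registration engine);
2. static signal `M0t (1 − e^(−t_sat/T1t))` with `t_sat = τ + PLD + δ(s)`
   evaluated at the **grid** slice (slice timing is a scanner property);
3. label volumes subtract the kinetic-model ΔM evaluated at
   `t = τ + PLD + δ(s)`: PV-weighted GM and WM tissue curves (tissue T1s
   1.3/1.1 s) plus the macrovascular component where aBV > 0. The
   saturation-recovery factor applies to the static signal only — the
   labelled bolus is fresh blood, not pre-saturated tissue;
4. multiplication by the empirical within-band factor `1 + g(p − 4.5)`
   and the bias field (both grid-locked, applied after motion);
5. additive homoscedastic Gaussian noise (Rician effects are negligible
   at the simulated SNRs).

Calibration images are treated as fully relaxed (TR 8 s ⇒ recovery factor
≈ 1, residual error < 1%), so they carry only the empirical gradient,
bias and noise — reproducing the observation that banding survives on
long-TR images.

Defaults and their rationale:

- `f_gm = 60`, `f_wm = 20` ml/100 g/min; `att_gm = 1.2` s, `att_wm = 1.5` s —
  typical adult grey/white values, deliberately offset from the fitting
  priors (1.3/1.6 s) so recovery tests cannot pass by prior reversion.
- `M0` 100 (GM) / 70 (WM) a.u.; blood `M0a = 100/λ` with λ = 0.9 ml/g; the
  pure-CSF value is derived by inverting the calibration equation so a
  noiseless phantom calibrates exactly (this is unit bookkeeping, not a
  hidden answer: the chain still has to recover it through the image).
- Empirical gradient default `g = −0.012`. Its magnitude is not published
  numerically anywhere we could adopt it from, so it is a package choice:
  negative so the mechanism opposes saturation recovery (later-excited
  slices are brighter under saturation recovery, so the residual mechanism
  must darken them for the two corrections to act in opposite directions),
  with magnitude set so the two nearly cancel at PLD 0.2 s — the
  qualitative behaviour reported for the real acquisition.
- `noise_sd = 0.5` a.u. (0.5% of GM M0): per-pair ΔM SNR ≈ 1.5, a
  realistic ASL operating point; recovery tests that specify "10% of peak
  ΔM" use 0.0806 a.u.
- Arterial arrival `att_arterial = 0.8` s for the macrovascular rods. With
  τ = 1.5 s the bolus then spans 0.8–2.3 s and is present during the first
  readout (1.70–2.23 s across slices) for **every** slice; an earlier
  arrival would leave the later-excited slices with literally zero
  arterial signal at all sampled times, making "detection" undefined
  rather than hard.
- Bias field: smooth in-plane bump (amplitude 0.1), constant along Z.
  In-plane receive-coil variation is the realistic part; a Z-varying bias
  would alias into the empirical-gradient estimate, whose removal in the
  real pipeline belongs to a bias-estimation stage that is an input here.

What the phantom does **not** emulate: realistic anatomy, susceptibility
or gradient distortion, background suppression, rotational motion, Rician
noise, dispersion of the labelled bolus, magnetisation-transfer physics of
the residual banding (only its linear signature). Passing the recovery
tests therefore demonstrates correctness of the algorithms under their own
generative assumptions — not robustness to everything real data can do.

## Saturation-recovery model and correction

`S(t_sat) = M0t (1 − e^(−t_sat/T1t))` is fitted voxelwise to all control
volumes jointly (their PLD spread gives 5 distinct saturation times per
voxel, spanning 1.7–4.76 s). The 2-parameter fit is solved by profiling:
for a candidate T1 the optimal M0 is closed-form, so the problem is a 1-D
search over T1 ∈ [0.1, 5] s on a 5 ms grid with parabolic refinement,
vectorised per slice. This reaches the same least-squares optimum as a
per-voxel trust-region solver at a small fraction of the cost (noiseless
recovery is exact to ~1e-5 s). Voxels with degenerate (constant) signal,
non-positive amplitude or a bound-pinned optimum are flagged invalid and
receive the mask-median T1 during correction, so the correction never
divides by an unfitted value.

The correction multiplies every voxel of every volume (label and control)
by `C(s, PLD) = (1 − e^(−(τ+PLD)/T1)) / (1 − e^(−t_sat(s,PLD)/T1))`,
normalising to the intensity at the nominal PLD. C = 1 at the first slice
of each band, C < 1 later in the band, and |C − 1| shrinks with PLD —
which is why this correction alone cannot remove banding at late PLDs.

An important consequence handled explicitly: the normalisation scales the
label–control difference by the same factor C as the static signal, while
the difference was physically sampled at the slice-adjusted time. The
subtraction stage therefore divides the fitted ΔM (and its standard
error) by C, so the kinetic model sees the true ΔM at the effective PLD.
Without this, noiseless CBF recovery would be biased by up to ~10% in
late-band slices.

## Empirical banding

On saturation-recovery-corrected (and bias-free) calibration images,
masked to grey+white matter (summed PV > 0.7), the mean masked intensity
of each slice is regressed on within-band position per band; the slope
divided by the band-mean intensity gives a relative gradient, averaged
over bands and then subjects. A single scalar `g` (not per-band pairs) is
identifiable from one calibration image and reproduces the described
behaviour; per-band parameterisations would require the unpublished exact
form. The correction divides by `1 + g(p − 4.5)`, whose band mean is
exactly 1: band-mean signal is preserved to first order (the residual is
the second-order term g²·var(p) ≈ 0.33% at g = 0.02). Estimation on the
extruded phantom is exact because masked slice composition is stationary;
an in-plane bias scales every slice equally and cancels in the relative
slope.

## Motion handling and subtraction

The per-volume translation trace is an input (the phantom supplies the
true trace; motion estimation is out of scope). Volumes are resampled back
to the reference grid (trilinear), and the banding corrections are applied
**motion-resolved**: the factor field of a volume is evaluated at the
slice each voxel occupied at acquisition, i.e. the slice-index field
shifted by that volume's Z translation, with sub-voxel shifts
interpolating between the factors of adjacent slices. Voxels whose
acquisition position fell outside the field of view in any volume are
excluded entirely. For sub-voxel shifts, correcting after interpolation is
itself an approximation (interpolation and multiplication do not commute);
it is exact for integer-slice motion.

The GLM design per PLD is a column of ones plus a ±1/2 control/label
contrast; with balanced volumes and no exclusions the estimate is exactly
the difference of group means (asserted to 1e-10), and the residual mean
square provides the per-voxel ΔM standard error used downstream. The
effective PLD map is `PLD + δ(z)` in reference geometry; per-volume PLD
jitter from motion is ignored beyond FOV exclusion — a documented
approximation. No information is shared across PLDs at this stage, so
ΔM(t) stays model-free until the kinetic fit.

## Kinetic inference

MAP under Gaussian likelihood with per-observation σ taken from the GLM
standard errors, floored at 1e-6 of the data scale. This makes the
prior/likelihood balance data-driven: noiseless data are fitted
essentially unregularised (noiseless recovery: f to 0.06%, ATT to
< 0.007 s), while pure-noise data revert to the ATT prior mean (1.3 s
within < 0.01 s on average) — both behaviours are tested.

Priors: ATT ~ N(1.3, 0.5²) s; arterial arrival ~ N(0.5, 0.3²) s;
perfusion noninformative; aBV under ARD. The prior SDs and the fixed
constants (T1 blood 1.65 s, labelling efficiency 0.85, λ = 0.9 ml/g) are
consensus values, configurable. ATT search bounds [0.1, 2.5] s are nearly
symmetric about the prior mean so truncation does not bias the
pure-noise reversion test.

Optimisation: the model is linear in (f, aBV) given the transit times, so
the fit is an exhaustive ATT grid (20 ms step) with closed-form weighted
amplitudes and parabolic refinement; the arterial arrival uses a 50 ms
grid. ARD alternates this with the MacKay precision update
`λ ← 1/(aBV² + posterior variance)` (≤ 20 iterations, tolerance 1e-4).
Analysis of the update's fixed points shows it asymptotes to a z = 1
evidence threshold — i.e. it retains noise-driven components in ~32% of
voxels no matter how long it runs — so the final pruning rule zeroes aBV
below max(1e-4, 2 posterior SDs). Measured on the mixed phantom at 10%
noise: sensitivity 1.00, specificity 0.97. Negative perfusion is allowed
during optimisation and clipped only in reports, avoiding boundary bias.

The apparent T1 includes the flow term `f/λ`, which requires perfusion in
s⁻¹; since the fit works in arbitrary units, the pipeline estimates the
CSF reference M0a *before* the kinetic fit (it needs only the corrected
calibration image) and the fit runs one refinement pass with
`f_si = f_au/M0a`. The term changes 1/T1app by ~1.4% at GM flow, so a
single pass suffices.

## Calibration

`M0a = mean(S_CSF) e^(TE/T2csf) e^(−TE/T2b) / λ_CSF` with λ_CSF = 1.15,
T2_CSF = 0.75 s, T2_blood = 0.15 s (3T values, configurable); no TR
saturation term (TR > 8 s ⇒ error < 1%). Only the first calibration image
is used; both are corrected. `CBF = 6000 f/M0a` — a global positive
scaling, so voxel rank order is untouched. The end-to-end noiseless round
trip recovers 60 ml/100 g/min to ~0.15%; the residual comes from
partial-volume voxels inside the CSF mask slightly diluting the reference
mean.

## Partial-volume correction

Two-tissue model `ΔM = pv_GM·B(f_GM, att_GM; T1 1.3 s) + pv_WM·B(f_WM,
att_WM; T1 1.1 s)`; the macrovascular component is deliberately omitted
(it is handled by the non-PVEc path). Priors: ATT ~ N(1.3, 0.5²) s for GM
and N(1.6, 0.5²) s for WM. Spatial regularisation is an explicit quadratic
6-neighbour penalty on each perfusion field in place of a spatial
variational method that estimates its own smoothness: the weight is
`smoothness × median per-voxel GM likelihood curvature` (default
smoothness 0.1), so the penalty tracks data SNR; it is configurable and 0
disables it. Because the phantom's true perfusion is uniform per tissue,
the penalty is nearly unbiased there; on real data it would smooth true
variation — the usual trade-off.

Optimisation is block-coordinate: given the transit times, the penalised
normal equations over all voxels form one sparse SPD system per sweep,
solved by Jacobi-preconditioned conjugate gradients with warm starts
(direct factorisation suffers severe fill-in on the 3D lattice); given
the amplitudes, each transit time is updated by grid search (50 ms) with
parabolic refinement. Sweeps stop at 1e-4 relative objective change
(max 50). Voxels with pv_GM + pv_WM < 0.01 are excluded; a small ridge
keeps the under-determined tissue of nearly-pure voxels finite, with the
spatial penalty propagating information from better-determined
neighbours.

## QC metrics and summaries

The band discontinuity index (BDI) is the mean absolute slice-mean
intensity jump across band boundaries divided by the same mean over
within-band neighbours, computed over a mask; ≈ 1 for band-free images,
defined as 1 for degenerate (constant) profiles. The QC report records
BDI per PLD after each correction stage, fit-failure counts and mask
sizes. Parcel summaries report n, mean and population standard deviation
(ddof = 0) per parcel and measure; label 0 is background and never
emitted.

## Problem sizes

Validation uses 24×24×60 phantoms (≈ 23k brain voxels, 8 400 pure-GM
voxels) for recovery and classification studies, and 16×16×60 phantoms
for the 20-subject cohort contrast — large enough for stable statistics
while keeping the full suite and the acceptance script each within a few
minutes on one core.

## Known limitations

- Motion is translation-only and known; rotational motion and motion
  estimation errors are not modelled.
- The iterative motion/banding re-estimation loop used with estimated
  motion collapses to a single pass here because the true trace is given.
- Bias correction divides by the supplied field in reference space; under
  motion the field is strictly grid-locked, leaving a small residual for
  in-plane shifts.
- The empirical banding model defaults to a single relative slope shared
  by all bands (a per-band estimate is available via
  ``fit_empirical_banding(..., per_band=True)``); a single coefficient
  set is used across cohorts, mirroring the pooled derivation.
- PVEc assumes the supplied PV maps are exact; PV estimation error
  propagates directly into tissue-specific estimates.
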