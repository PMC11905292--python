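# hcpasl-lite

Processing of simultaneous multi-slice (SMS), multi-delay pseudo-continuous
arterial spin labelling (PCASL) MRI: banding-artefact correction,
motion-aware label–control subtraction, kinetic-model inference of
perfusion (CBF), arterial transit time (ATT) and macrovascular blood
volume (aBV), CSF reference-region calibration, and partial-volume
correction (PVEc) — together with a synthetic phantom that simulates the
acquisition with known ground truth, so every stage can be validated by
parameter recovery without any real data.

It is aimed at perfusion-MRI methodologists who want a compact, fully
tested reference for the bespoke steps of high-resolution SMS PCASL
processing, at the 2.5 mm multi-delay protocol used by large lifespan
imaging studies (label duration τ = 1.5 s; PLDs 0.2/0.7/1.2/1.7/2.2 s
repeated 6/6/6/10/15 times; 60 slices in 6 SMS bands of 10; 59 ms per
slice excitation).

## The models

**Banding.** A pre-saturation pulse precedes labelling, so the static
tissue signal at excitation follows saturation recovery
`S = M0t (1 − e^(−t_sat/T1t))` with `t_sat = τ + PLD + δ(s)` and
`δ(s) = (s mod 10) · 59 ms`: later-excited slices within each SMS band are
brighter, with a discontinuity at every band boundary. The model is fitted
voxelwise to the control images and the series is normalised to the
intensity each slice would have had at the nominal PLD. A second, residual
banding mechanism — an approximately linear within-band intensity gradient
`1 + g·(p − 4.5)` that survives saturation-recovery correction — is
estimated from grey/white-masked calibration images and divided out. The
two mechanisms act in opposite directions and nearly cancel at the
shortest PLD; only their combined correction removes banding at every PLD.

**Subtraction.** Per PLD, label–control differencing is an ordinary least
squares fit with a static regressor and a ±1/2 perfusion regressor, so the
coefficient equals the control-minus-label difference ΔM. Correction
factors are evaluated at the slice each voxel occupied at acquisition
(motion-resolved, using the known per-volume translations), and voxels
that left the field of view at any timepoint are excluded.

**Kinetics.** ΔM(t) follows the general kinetic model for PCASL: zero
before arrival (t < ATT), inflow with apparent relaxation
`1/T1app = 1/T1t + f/λ` during bolus delivery, washout afterwards; plus a
macrovascular compartment `2α·M0a·aBV·e^(−t/T1b)` while the label occupies
the artery. Voxelwise inference is MAP with a N(1.3 s, 0.5 s) ATT prior,
a noninformative perfusion prior and an automatic relevance determination
(ARD) prior that zeroes aBV in non-arterial voxels. Estimates revert to
the prior mean where the data are uninformative.

**Calibration.** `M0a = mean(S_CSF) · e^(TE/T2csf) · e^(−TE/T2b) / λ_CSF`
from the ventricular CSF of the first long-TR calibration image, then
`CBF = 6000 · f / M0a` in ml/100 g/min.

**PVEc.** ΔM is modelled as `pv_GM·B_GM + pv_WM·B_WM` with tissue-specific
ATT priors (1.3/1.6 s) and a first-order spatial penalty on the perfusion
fields, fitted by block-coordinate descent (sparse linear solves for the
amplitudes, grid search for the transit times).

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
import hcpasl_lite as h
from hcpasl_lite.pipeline import process_dataset, ProcessOptions
from hcpasl_lite.pvec import masked_tissue_mean

protocol = h.default_protocol()
truth = h.make_phantom((24, 24, 60), protocol, seed=2)   # banded, biased, noisy
series, calib, _ = h.simulate_dataset(truth, protocol)

res = process_dataset(series, calib, truth.pv_gm, truth.pv_wm, truth.csf_mask(),
                      bias_field=truth.bias_field, options=ProcessOptions(pvec=True))
maps = res["perfusion"]
print(res["empirical_gradient"], res["m0_blood"])
print(masked_tissue_mean(maps.perfusion, truth.pv_gm, 0.9),
      masked_tissue_mean(maps.att, truth.pv_gm, 0.9))
```

prints (formatted):

```
estimated empirical gradient: -0.0120 (truth -0.0120)
blood M0 from CSF: 110.2 a.u. (truth 111.1)
calibration BDI: 8.99 -> 0.48
GM CBF 62.8 ml/100g/min (truth 60.0); GM ATT 1.248 s (truth 1.200)
PVEc GM CBF 63.1 vs non-PVEc 59.8 ml/100g/min over mixed voxels
```

The within-band gradient injected by the simulator is recovered exactly;
the band discontinuity index (BDI — the ratio of inter-band to intra-band
slice-mean jumps, ≈ 1 for band-free images) falls from ~9 to ~1 after
correction; calibrated grey-matter CBF and ATT come back close to the
simulated ground truth at this noise level; and PVEc raises GM CBF over
the partial-volume-diluted estimate, as expected for mixed voxels.

The same pipeline is available from the shell:

```bash
hcpasl-lite sim --shape 24 24 60 --seed 2 --out phantom/
hcpasl-lite run config.yaml          # see RunConfig for the YAML fields
```

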