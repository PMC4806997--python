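# dixonfgt

Percent fibroglandular tissue (%FGT) measurement from two-point Dixon
breast MRI, together with a digital-phantom acquisition simulator that
makes every stage of the measurement testable without patient data.

Breast density — the fraction of the breast occupied by fibroglandular
tissue (FGT) rather than fat — is a strong breast-cancer risk factor.
Dixon MRI separates water and fat images arithmetically from in-phase
and opposed-phase echoes, turning density measurement into a
voxel-by-voxel water-fraction sum that naturally accounts for partial
volume. The catch is calibration and sequence choice: a 100%-water and
a 100%-fat voxel do not produce equal signal, and the residual
weighting of the acquisition (flip angle, sequence family, fat spectral
complexity) biases the result. This package implements the full
measurement chain and the statistics used to characterize those biases,
for medical-imaging scientists who want to prototype, validate or
stress-test Dixon density protocols.

## The measurement

For each breast, a correction factor is calibrated from a standardized
30×30 mm² region of interest at the breast centre, in a central slice
containing both tissue classes:

    c = F_max / W_max

where `F_max`, `W_max` are the maximum fat- and water-image intensities
in the ROI. The corrected per-voxel water fraction is

    WF(i,j,k) = c·W(i,j,k) / (c·W(i,j,k) + F(i,j,k))

and, over the segmentation mask M with voxel volume v,

    FGT volume = Σ_M WF · v,   %FGT = 100 · FGT volume / (|M| · v).

Repeatability is summarized by Bland-Altman statistics: with σ_d the
sample SD of paired test-retest differences, the coefficient of
repeatability is CoR = 1.96 σ_d and the within-subject coefficient of
variation is CoV = σ_d / (√2 · x̄) · 100%.

The simulator generates two-breast phantoms with known per-voxel FGT
fraction and synthesizes three acquisition presets at 1.5 T: a
PD-weighted and a T1-weighted 3D spoiled gradient-echo Dixon
(TR 7.34 ms, TE 4.77/2.39 ms, flip 4° / 25°, 1.3×1.3×1.0 mm³) and a
spin-echo Dixon with an echo train (TR 500 ms, TE 12 ms,
0.8×0.8×7.0 mm³), with a six-peak triglyceride fat spectrum, Rician
noise, optional coil-sensitivity bias and multiplanar reformatting.
See `docs/methods.md` for the signal model and all defaults.

## Worked example

```python
import numpy as np
from dixonfgt import (
    PhantomSpec, TissueProperties, generate_phantom, simulate_dixon_acquisition,
    two_point_separation, body_mask, pectoral_cut_and_split,
    select_calibration_roi, correction_factor, water_fraction_map, fgt_summary,
    true_fgt_percent,
)
from dixonfgt.image import VolumeImage

spec = PhantomSpec(rng_seed=7)           # two breasts, blob-mixture composition
phantom = generate_phantom(spec)

echoes = simulate_dixon_acquisition(phantom, TissueProperties(),
                                    seq="hr-gre-pd", noise_sd=0.02, rng_seed=7)
pair = two_point_separation(echoes, mode="complex")

in_phase = VolumeImage(np.abs(echoes.in_phase.data), echoes.in_phase.spacing)
mask = body_mask(in_phase, threshold="auto", erosion_iters=1)
left, right = pectoral_cut_and_split(mask, spec.chest_wall_plane_index)

roi = select_calibration_roi(pair, right)
c = correction_factor(roi)
wf = water_fraction_map(pair, c, right)
result = fgt_summary(wf, right, c=c.c)

print(f"correction factor c = {c.c:.2f}")
print(f"FGT volume   = {result.fgt_volume_cm3:.1f} cm^3")
print(f"breast volume = {result.total_volume_cm3:.1f} cm^3")
print(f"%FGT measured = {result.pct_fgt:.1f}  (ground truth {true_fgt_percent(phantom, 'R'):.1f})")
```

Output:

```
correction factor c = 1.03
FGT volume   = 15.6 cm^3
breast volume = 54.6 cm^3
%FGT measured = 28.6  (ground truth 27.6)
```

The correction factor near 1 reflects the PD-weighted acquisition's
nearly tissue-independent signal; the measured %FGT lands within one
point of the phantom's ground truth despite 2% Rician noise.

A command-line interface mirrors the library:

```bash
dixonfgt simulate --preset hr-gre-pd --seed 1 --out sim/
dixonfgt segment --in sim/in_phase.nii.gz --threshold auto --cut 44 --out seg/
dixonfgt quantify --water sim/water.nii.gz --fat sim/fat.nii.gz \
                  --mask seg/mask_R.nii.gz --c auto
dixonfgt run --experiment comparison --seed 1 --out run/
```

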