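# Methods

## Scope and pipeline

`dixonfgt` measures percent fibroglandular tissue (%FGT) from two-point
Dixon breast MRI and provides a digital phantom plus acquisition
simulator so the whole chain can be validated against known ground
truth. The chain is:

1. **phantom** — voxelized anatomy with known per-voxel FGT fraction;
2. **simulate** — complex in-phase/opposed-phase echo pairs from
   steady-state signal equations;
3. **recon** — two-point fat-water separation;
4. **segment** — threshold + despeckle body mask, straight coronal
   pectoral cut, midsagittal left/right split; translation registration
   and mask transfer between datasets;
5. **quantify** — ROI calibration `c = F_max/W_max`, corrected water
   fraction `WF = cW/(cW+F)`, FGT volume and %FGT;
6. **stats** — Bland-Altman repeatability, paired *t*, Pearson *r*,
   repeated-measures ANOVA, cohort summaries.

## Phantom and coordinate conventions

Axis order is (x, y, z) = (left-right, anterior-posterior,
superior-inferior); voxel centres sit at `index × spacing`; all masks
are half-open integer index sets. The torso section is a chest-wall
slab at coronal index ≥ `chest_wall_plane_index` with two
half-ellipsoid breasts bulging anteriorly from that plane; the right
breast occupies the lower x indices. Scan orientation (axial slices
along z) is a package convention — nothing in the measurement depends
on it, but it fixes what "central slice" and "in-plane" mean for the
calibration ROI.

Composition models for the fibroglandular fraction `v ∈ [0,1]`:
`uniform` (constant, useful for exact arithmetic checks), `blobs`
(random spheres of FGT-rich tissue in a fat background, or the inverse
for dense breasts — the workhorse, since it produces both tissue
classes for ROI calibration and realistic spatial structure), and
`field` (caller-supplied array). The chest wall is assigned
`v = 0.85` (muscle is mostly water); it is excluded from every breast
measurement by the pectoral cut but matters for segmentation and
phase-alignment realism. Ground truth %FGT per breast is
`100·mean(v)` over the breast label, exact by construction.

## Signal model

Per voxel, water magnetization uses the family's steady-state equation:

* spoiled gradient echo (GRE-SPGR):
  `S = PD · sin α · (1 − E1)/(1 − E1 cos α)`, `E1 = exp(−TR/T1)`;
* spin echo: saturation recovery `S = PD · (1 − E1)`.

Transverse decay multiplies by `exp(−TE_decay/T2)`. **Both echoes decay
at the in-phase echo time**: the ~2.4 ms between the two Dixon readouts
is kept for fat-water *phase* evolution but neglected for amplitude.
This matches the assumption built into the two-point separation
arithmetic (equal species amplitudes at both echoes) and makes the
idealized invariants exact — e.g. a pure-water voxel has identical
in-phase and opposed-phase magnitude. For the spin-echo family the
chemical shift is refocused at the spin echo, so the in-phase echo has
zero fat-water phase and the opposed echo is a readout shifted by half
a cycle of the tuned fat-water frequency; echo-train T2 weighting is
modelled by a single effective echo time
`TE + k·echo_spacing` with configurable `k` (default 0, i.e. decay at
the nominal TE — the data the package emulates say only that the echo
train "may" add T2 weighting, so the default adds none).

Fat is a multi-peak species: the voxel fat signal is the
amplitude-weighted complex sum over spectrum peaks
`Σ_p a_p exp(2πi f_p τ)` at the echo's phase-evolution time τ. Two
spectra are built in:

* **six-peak** (default): the standard published triglyceride model,
  peaks at −3.80, −3.40, −2.60, −1.94, −0.50, +0.60 ppm relative to
  water (amplitudes 0.087/0.693/0.128/0.004/0.039/0.048, normalized),
  converted to Hz at 1.5 T;
* **single-peak**: one resonance at the *tuned* fat-water shift
  −1000/4.77 Hz ≈ −209.6 Hz — exactly the shift the preset echo times
  (4.77 ms in-phase, 2.39 ms opposed) are timed for, so that idealized
  tests cancel perfectly. (The methylene peak proper, −217 Hz, would
  leave a spurious residual that is really a multi-peak effect.)

Complex Gaussian noise of SD `noise_sd × mean tissue in-phase
magnitude` is added to both echoes before any magnitude operation, so
magnitude images are Rician. Default `noise_sd = 0.02` (SNR ≈ 50 in
tissue), a typical value for 1.5 T breast imaging at these voxel
volumes. An optional low-order polynomial multiplicative bias field
emulates coil sensitivity; the default is none, because the calibration
ROI is deliberately placed at the breast centre to sidestep coil
effects.

Default tissue parameters are literature-typical for 1.5 T and
configurable: water/FGT T1 = 1266 ms, T2 = 58 ms; fat T1 = 296 ms,
T2 = 53 ms; relative proton densities 1.0/1.0. They are *not* derived
from the emulated study, which published no relaxation values; absolute
correction factors therefore agree with the published ones only in
magnitude (simulated c ≈ 1.0–1.3 for the PD-weighted preset, ≈ 2.7–3.6
for the 25° preset, ≈ 2.1–2.5 for the spin echo, against published
cohort means 1.21, 3.27, 2.91).

### Why the sequence biases emerge

With a perfect calibration and a single fat peak, `WF = cW/(cW+F)`
equals the voxel's water fraction identically, for any weighting — the
calibration is exactly what removes T1 weighting. The simulated biases
arise from two real mechanisms:

* **multi-peak fat**: the secondary peaks are neither in phase at the
  nominal in-phase time nor opposed at the opposed time, so the
  separation misassigns part of the fat signal to water. The
  misassigned fraction is multiplied by `c` in the corrected WF, so the
  same spectral leak produces a larger %FGT excess at stronger T1
  weighting, and the spin-echo preset — whose in-phase echo is a
  *coherent* spin echo, maximizing the opposed-echo mismatch — shows
  the largest excess;
* **Rician noise floor**: in pure fat the water image contains a noise
  floor that `c` amplifies.

Both effects scale with the amount of fat in the breast, which is why
the spin-echo excess grows as true density falls.

## Reconstruction

Complex mode computes `W = |(IP+OP)/2|`, `F = |(IP−OP)/2|` after
aligning the opposed echo's global phase to the in-phase echo.
The per-voxel relative phase sits near the instrumental offset φ in
water-dominant voxels and near φ+π in fat-dominant ones, so a plain
signal-weighted phase average can cancel between the two populations;
the estimator therefore squares the per-voxel phasors (angle doubling)
to make both branches coherent, halves the angle, resolves the
remaining π ambiguity towards the smaller rotation (a genuine receiver
offset is small; removing π would swap water and fat), and refines the
estimate on clearly water-dominant voxels (`W > 2F`). Magnitude mode
(`W = (|IP|+|OP|)/2`, `F = (|IP|−|OP|)/2` clipped at 0, clip count
logged) is retained for vendor magnitude inputs; it cannot distinguish
pure fat from pure water and is only meaningful where water dominates.

## Segmentation

Thresholding (explicit value or Otsu "auto") is followed by
`erosion_iters` rounds of 6-connected binary erosion and a
morphological reconstruction of the survivors within the thresholded
mask: isolated background specks thinner than the erosion vanish while
the body boundary — including the skin — is restored exactly. The
largest connected component is kept. The pectoral cut removes all
voxels at or posterior to the cut index (half-open); the split plane is
the grid midline by default. When a cut index is carried to a coarser
grid it is converted with a floor (`cut_index_on_grid`), keeping only
voxel centres strictly anterior to the physical plane so that
interpolated chest-wall signal can never survive the cut.

Registration is an exhaustive integer-voxel grid search maximizing
mutual information (32-bin joint histogram over the overlap region)
with per-axis quadratic sub-voxel refinement. MI is invariant to
monotone intensity remapping, which is what lets one segmentation be
transferred across datasets with different contrast; transfer uses
nearest-neighbour resampling.

## Quantification

The ROI is a 30×30 mm² square (nearest-integer voxel count per axis)
centred on the mask's in-plane centroid, in the axial slice nearest the
mask centroid that contains both tissue classes — operationalized as at
least 5% of in-mask ROI voxels above and below an uncorrected water
fraction of 0.5 (the qualifying rule is a package choice; "contains
fat and water" is all the emulated protocol specifies). `F_max` and
`W_max` are plain maxima over in-mask ROI voxels (a 99th-percentile
robust mode is available for noisy data). Calibration, like
segmentation, is done separately and independently per breast per
dataset. Only the water image is scaled by `c`; the fat image enters
the denominator raw. Voxels with `cW + F = 0` contribute WF = 0 and
are counted in the log. The sensitivity analysis recomputes the map
and summary from scratch at `c(1 ± δ)`, default δ = 0.15.

## Reformatting

`reformat` resamples trilinearly onto a voxel-centre-aligned grid
covering the same physical extent (`ceil(extent/spacing)` voxels per
axis). Axes being coarsened are first smoothed with a Gaussian whose
variance matches the wider target voxel
(`σ = √((r²−1)/12)` source voxels for spacing ratio r): a 7 mm
reformatted slice represents the average over its slab, not a point
sample between 1 mm slices. Without this anti-aliasing step,
resampling heterogeneous anatomy to 7 mm slices point-samples a
different tissue subset and the high/low-resolution agreement that
thick-slice Dixon measurement relies on is destroyed. Constants are
preserved exactly; resampling at unchanged spacing is the identity.

## Statistics

σ_d uses the n−1 sample formula; CoR = 1.96 σ_d; CoV = σ_d/(√2 x̄)·100
with x̄ the mean of per-pair means. The √2 denominator (rather than 2)
is chosen because it makes a CoV and CoR expressed in the same units
mutually consistent — `implied_cor_from_cov` is its exact inverse, and
the published repeatability summaries the package ships as reference
values (%FGT CoV 4.3%, CoR ±4.3% at cohort means 36.3/35.4) are
consistent only under √2. ANOVA is implemented as one-way repeated
measures (datasets are a within-breast factor), via
`statsmodels.stats.anova.AnovaRM`; paired *t* and Pearson *r* come from
scipy. Breasts are treated as independent observations, and no
multiple-comparison correction is applied, matching the emulated
analysis plan. Cohort comparison consumes any per-breast CSV with
columns `subject, laterality, dataset, fgt_cm3, total_cm3, pct_fgt`.

## Experiments and problem sizes

`run_experiment` drives three studies: *repeatability* (each subject
simulated twice with a random rigid repositioning jitter, default
±2 mm, independent noise, and fully independent processing),
*comparison* (five datasets per subject: the two gradient-echo presets
natively, their 0.8×0.8×7.0 mm reformats, and the reformatted
spin-echo acquisition; one segmentation per resolution, transferred
across same-grid datasets after registration) and *sensitivity*
(±15% correction-factor perturbation). Default cohorts use six
subjects on a 72×48×36 grid at 1.3×1.3×1.0 mm — small enough that a
full experiment runs in seconds, large enough that each breast spans
several 7 mm slices. The density sweep used by the validation suite
uses a 96×64×80 grid (five phantoms spanning ≈10–90 %FGT) so that the
coarsened z-axis retains ~11 slices. Every run writes a manifest
(config, hash, seed, version) sufficient to reproduce it.

## What the synthetic data does and does not show

The phantom has sharp two-class composition (plus partial-volume voxels
introduced by reformatting), perfectly homogeneous B0, no motion, no
parallel-imaging artifacts, no skin-versus-gland distinction and a
simple half-ellipsoid geometry. Passing tests therefore demonstrate
the *internal* correctness of the measurement chain and the *mechanism*
of the sequence biases, not clinical accuracy: simulated repeatability
(CoR ≈ 2–3 %FGT under default noise and jitter) is better than the
published in-vivo ±4.3%, whose extra variance includes coil
reconfiguration, arm repositioning and operator interaction that the
simulator does not model. The per-volunteer supplementary table of the
emulated study is not redistributable, so the cohort statistics can be
recomputed only for user-supplied data in the same layout.

## Other limitations

Two-point separation assumes no B0-induced phase errors (three-point
methods and B1 bias-field correction are out of scope). The vendor's
actual separation algorithm is unknown; complex mode assumes swap-free
phase-consistent echoes. The magnitude-mode dialect is only valid
where water dominates. Tissue parameters and the fat spectrum are
literature defaults, not fitted values.
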