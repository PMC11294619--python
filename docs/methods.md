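# Methods

This note documents the models behind each module, the parameters that
matter, the numerical choices made where the design was genuinely open, and
what validation on synthetic data does and does not establish.

## Synthetic data: what it emulates

The generators reproduce the *statistical structure* of a post-mortem
primate study — not tissue realism.

**Neuron images** (`generate_cell_image`). One soma per image, modelled as
an axis-aligned ellipse with a strictly interior elliptical nucleus
(defaults: ~30 × 24 µm soma, ~10 × 8 µm nucleus at 0.2 µm/px on a 256 × 256
grid — macaque dopaminergic scale). Puncta are isotropic Gaussian spots of
σ = radius/2 truncated at 3σ, so each has an unambiguous true area πr²;
the default radius 0.4 µm is lysosome-scale. Placement is rejection
sampling (≤ 1000 retries per punctum) restricted to the requested
compartment, with centre-to-centre spacing ≥ 2.5 radii so that noiseless
detection is unambiguous, and one radius of clearance from the soma border
so no spot is clipped. Noise follows the standard fluorescence camera
model: optional Poisson resampling of the signal followed by additive
Gaussian read noise. The study this emulates reports no intensity
statistics for its images, so background (50), peak amplitude (150 above
background) and read noise (SD 5) are free, realistic-scale choices —
fixed once, not claims about any real acquisition.

Not emulated: point-spread anisotropy and 3-D stacks (analysis is 2-D on
one z-plane by design), tissue autofluorescence texture, multi-cell
crowding, chromatic shift. Passing tests therefore demonstrate the
*correctness of the measurement chain*, not robustness to every real-world
artefact.

**Neuron fields** (`generate_neuron_field`). Points uniform in a
6000 × 4000 × 3000 µm box (≈ nigral scale), cut into 50 µm sections; each
neuron belongs to exactly one section — the discrete equivalent of
counting a cell only where its nucleolus lies. A 1-in-12 systematic series
with seed-drawn phase is flagged as sampled. Uniformity is the situation
in which the fractionator should be exactly unbiased; clustering only
affects variance, not bias, and is not modelled.

**Stained sections** (`generate_dab_image`). Random discs are unioned until
the stained-pixel count reaches `round(f·N)` exactly (the last disc is
trimmed rim-first), so the recorded true surface fraction is exact at the
pixel level and recovery can be asserted to one-pixel quantisation.

**Elemental maps** (`generate_elemental_map`). I.i.d. normal pixel
concentrations clipped at zero; default geometry 100 × 100 pixels at 5 µm
step = a 500 × 500 µm field, matching a typical synchrotron-XRF raster of
the substantia nigra. Spatial correlation of real elemental maps is not
modelled — ROI means are insensitive to it.

**Group tables** (`generate_group_table`). Normal two-group data with
defaults n = 6 vs 4 hemispheres, control mean 100 (percent-of-control
scale), effect −30, SD 8 — pilot-cohort sizes typical of non-human-primate
work, which is exactly the regime where the statistics module's
small-sample behaviour matters.

All generators drive every random choice from one explicit integer seed;
identical parameters and seed give bit-identical outputs.

## Puncta quantification

Pipeline order per cell: QC filter → compartment partition → channel
masking → detection → distances → aggregation.

- **QC ratio** (`qc_ratio_filter`): cytoplasm area / nucleus area must be
  ≥ 2.0 (configurable). The criterion is read as a minimum; cells failing
  it are logged and never measured.
- **Perinuclear band** (`partition_compartments`): the literature rarely
  defines the perinuclear/cytosolic boundary, so it is an explicit
  parameter — a Euclidean-distance band (default 2 µm) from the nucleus
  border, computed on the exact pixel distance transform. Perinuclear and
  cytosolic masks tile the cytoplasm exactly, which makes count
  conservation (whole cell = perinuclear + cytosolic) structural rather
  than statistical.
- **Detection** (`detect_puncta`): Gaussian pre-filter (σ = 1 px, standard
  spot-calling practice), threshold, 8-connected labelling, watershed
  splitting of touching components at local intensity maxima ≥ 3 px apart,
  and a 2-px minimum area floor. The default automatic threshold is
  **robust-background**: median + 4·(1.4826·MAD) of the smoothed
  within-mask pixels. Otsu-style histogram splitting is also available but
  is *not* the default for a measured reason: with puncta occupying only a
  few percent of the soma the Otsu criterion collapses onto the background
  mode, which both merges close spots (threshold too low) and floods the
  count with noise components at moderate SNR. With the robust default the
  pipeline recovers noiseless catalogues exactly and keeps the mean
  absolute count error well under 5% at peak-SNR 5 (both properties are
  asserted over 100 seeds in the test suite). On a zero-MAD (flat,
  noiseless) background the robust rule degenerates and the code falls
  back to Otsu, which is safe there.
- **Compartment assignment**: by the compartment containing the punctum's
  centre of mass; a centroid overlying the nucleus is assigned perinuclear
  (its distance to the nucleus is zero, inside any positive band).
- **Distances**: the nucleus is summarised by the moment-matched ellipse of
  its mask; distance-to-border = distance-to-centre − (a + b)/2. The mean
  radius is a deliberate simplification (the exact point-to-ellipse
  distance is a quartic); for near-circular nuclei the error is second
  order in the eccentricity.
- **Conventions**: 0-based (row, col) indices; physical position of a pixel
  is (index + 0.5) × pixel size; areas are pixel counts × pixel-size².
  Thresholds are meant to be chosen once per stain and stored in the
  analysis configuration, then applied to every image of a study.

## Stereology

`count_frame` implements the unbiased counting frame for point particles:
counted iff `x0 < x ≤ x0+w` and `y0 < y ≤ y0+h` (inclusion on top/right
edges, exclusion on left/bottom). Abutting frames partition the plane, so a
tiling counts every point exactly once — asserted on 10 000 random points.

`place_sampling_grid` lays frames at one per grid cell: origins at
`offset + k·(dx, dy)` for every origin inside the region, with the offset
drawn uniformly in one grid cell per section (systematic uniform random
sampling). This origin-in-region convention means a band up to one frame
width at the low-x/low-y region border is slightly under-sampled; at the
default design on a 6000 × 4000 µm field the measured bias of the full
estimator is ≈ −1.3%, well inside the 5% validation band, and shrinks with
region size. The alternative (extending the grid one cell beyond the
region) removes the residual bias but places frames outside the delineated
region; the simpler convention was kept.

`fractionator_estimate` scales ΣQ⁻ by 1/(ssf·asf·tsf). The thickness
sampling fraction defaults to 1.0 — planar counting with no guard zones —
because dissector height and guard-zone geometry are deployment-specific;
it is exposed as a parameter. At the default design the multiplier is
12 × 30 = 360 per counted cell.

## Densitometry

Mean grey, stained-surface ratio (fraction of ROI pixels ≥ threshold) and
ppm-map ROI means are direct arithmetic on masked pixels. Colour
deconvolution of RGB chromogen images is out of scope: the operative
quantity is the thresholded surface ratio on a single intensity channel,
with stain-positive defined as ≥ threshold so the ratio is monotone
non-increasing in the threshold and bounded in [0, 1].

## Estimation statistics

- **t-test**: Student's pooled-variance two-tailed test (df = nₐ + n_b − 2),
  delegated to `scipy.stats.ttest_ind` and cross-checked against the
  closed-form formula to 1e-10 in the tests; Welch available behind a
  flag. Zero pooled variance returns t = 0, p = 1 for equal means and is an
  error otherwise.
- **Bootstrap** (`bootstrap_mean_diff`): within-group resampling with
  replacement, default 5000 resamples, fully seed-deterministic. The
  default interval is **studentized (bootstrap-t)**: quantiles of
  `(d* − d)/se*` mapped back through the plug-in standard error. This
  choice is empirical: at the pilot sample sizes this package targets
  (n = 6 vs 4) the plain percentile interval covers a true effect only
  ~87–88% of the time at nominal 95%, while the studentized interval
  measures ~95% (2000-simulation check in the test suite). Percentile and
  BCa intervals remain available for compatibility with the
  estimation-graphics tradition; the resample distribution itself is
  identical across methods and is what the Gardner–Altman curve displays.
- **z-profiles** (`zscore_profile`): per variable,
  z = (x − mean_ctrl)/sd_ctrl with the sample (n−1) SD. The pooled control
  row is set to exactly zero — it represents the z of the control mean.
  Variables with zero control SD are flagged and skipped rather than
  propagating infinities.
- **Caveat carried from the design**: the observational unit is the
  hemisphere; hemispheres of one animal are treated as independent, with
  no hierarchical correction, and no multiplicity adjustment is applied
  across endpoints. These mirror common pilot-study practice and are
  limitations, not endorsements.

## Validation scale

The bundled validation runs at desk scale, chosen so the full suite
finishes in well under a minute of compute per block: 100 cells per imaging
condition, 200 simulated fields of 12 000 neurons for the fractionator,
10 000 null simulations for the t-test calibration, 2000 for bootstrap
coverage, 50 map pairs for the elemental contrast. `scripts/acceptance.py`
recomputes all of it from a single seed.

## Known limitations

- 2-D single-plane analysis by construction; no optical-dissector stepping
  in z and no coefficient-of-error estimators beyond empirical Monte-Carlo
  spread.
- Automatic soma/nucleus segmentation is out of scope — masks are inputs,
  as in the manual workflow the pipeline mirrors.
- The robust-background threshold assumes puncta are a minority of cell
  pixels; a cell whose marker fills most of the soma needs a fixed,
  config-stored threshold instead.
- Generator realism bounds what green tests prove (see above); results on
  real tissue additionally depend on staining quality, segmentation and
  acquisition choices that the synthetic cohort does not model.
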