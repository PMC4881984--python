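# Methods

This note documents the models and procedures implemented in
`phagoquant`, the choices made where the underlying measurement
conventions were open, and what the synthetic benchmarks do and do not
establish about real data.

## Census metrics

A *census* is one sampled tissue region: total apoptotic cells
(pyknotic/karyorrhectic nuclei), the subset enclosed in a microglial
pouch, the microglia count, a histogram of microglia by pouch number,
the region volume, and optionally per-cell distances to the nearest
microglial process.

The metrics are ratios of these counts:

    Ph index     = apo_ph / apo_tot                      in [0, 1]
    Ph capacity  = sum_n n * count_n / mg                 ppu
    net phag.    = mg * Ph capacity                       cells
    Ph/A         = net phag. / apo_tot                    -
    fold change  = Ph/A / mean(Ph/A over baseline group)

Conventions:

* Pouch histograms are stored as **counts**, never proportions;
  proportions are derived at compute time.  Cells with zero pouches are
  implicit (total minus histogram sum), so input tables may list only
  phagocytic cells.
* All internal values are fractions; `%` formatting belongs to report
  layers.  This removes any chance of double scaling.
* Fold change normalizes to the **mean** of a named baseline group; the
  baseline is configuration, never inferred from the data.
* A zero denominator (no apoptotic cells, no microglia) makes the metric
  *unestimable*, not zero: the functions raise `UndefinedMetricError`
  with a reason code, and the tabular summary emits NaN plus the reason.
  Treating "no apoptosis detected" as Ph index 0 would claim a
  phagocytosis failure where there was nothing to phagocytose.
* Default distance bins are [0, 0.5), [0.5, 3), [3, 10), [10, inf) µm —
  touching, near, intermediate, far; overridable.

## Clearance time

The clearance time τ is the mean residence time of an apoptotic cell in
tissue.  At steady state, removal flux = present/τ, so over a window Δt

    cleared = present * Δt / τ        and inversely
    τ = present(t2) * Δt / cleared.

The two-group inference assumes a pulse-labeled cohort of **equal total
size** in both groups (same labeling, survival unaffected): the
reference group's cleared count follows from its known τ_ref, the total
is present_ref + cleared_ref, the test group's cleared count is total −
present_test, and τ_test follows.  The assumption is asserted: if
present_test exceeds the inferred total the inference refuses with a
diagnostic rather than returning a negative time.

Parameter defaults: τ_ref = 1.5 h (physiological clearance in the adult
hippocampal neurogenic niche) and Δt = 24 h (a one-day window between
challenge and sacrifice).  Both are ordinary, logged parameters —
`RunReport.defaults_used` records when they were filled in.

**Known limitation.** The inference is exact only for inputs satisfying
its own model.  Feeding it two *continuous-production steady-state*
cohorts violates the equal-total premise structurally: over a window Δt
each group's "present + cleared" is rate·(τ + Δt), which differs between
groups by rate·(τ_test − τ_ref).  At τ_test = 6.3 h, Δt = 24 h this
inflates the inferred time by ~25 %.  The cohort simulator is therefore
used to validate the *formula* (single-cohort recovery of τ), while the
two-group route is exercised on group counts.

## 3-D process motility

Input: a registered 4-D stack (t, z, y, x) with anisotropic voxels
(default 0.1 × 0.1 × 1 µm) and a fixed frame interval (default 1.5 min).
Registration/drift correction is explicitly upstream of this package.

Per process and frame:

1. **Reorientation.**  The manually selected ROI is cropped and rotated
   in-plane (bilinear resampling) so the process axis runs along y.
   Requires square xy pixels.
2. **Border detection** per (z, y) line: the x intensity profile is
   lightly smoothed (Gaussian, σ = 1.5 px), the peak found, and the
   borders placed where intensity first falls to
   background + 0.5·(peak − background) on each side (sub-pixel, linear
   interpolation), optionally snapped to the nearest inflexion point
   (second-difference sign change) within 3 px.  Half-max is the
   standard width convention; all knobs are exposed (`BorderParams`).
   A peak at the profile edge is rejected — the prominence criterion
   needs flanking pixels, and a process touching the ROI border is not
   measurable.
3. **Presence map.**  A (z, y) line contains the process if its peak
   clears background + 0.3·(dynamic range).  The peak map is smoothed
   *along y* (σ = 2 lines) before thresholding: a process is continuous
   along its axis, so this keeps the upper/bottom slices (z_U, z_B)
   stable against single-line noise, which would otherwise make the
   center slice flicker.  A line must additionally clear the bar with
   its own unsmoothed peak (ends stay crisp), and only the largest
   contiguous run of lines is kept (isolated detections are noise).
4. **Center points.**  Per line, z_C = (z_U + z_B)/2.  If z_C is an
   integer, x_C = (x_R + x_L)/2 at that slice; if half-integer
   ("virtual slice"), x_R and x_L are first averaged over the two
   flanking slices.  A missing central slice is a *gap* and the line is
   skipped (counted in the skeleton's metadata).
5. **Centerline smoothing.**  x_C gets a 7-line (0.7 µm) moving
   average; z_C a 21-line (2.1 µm) one.  z_C is quantized at half a
   z-step (0.5 µm against 0.1 µm line spacing), so without averaging
   every quantization jump adds ~0.4 µm of spurious length to the
   skeleton; the wider window converts the staircase into a sub-slice
   estimate.  Window sizes are parameters and are recorded in run
   metadata.
6. **Length** = Σ over consecutive center points of
   √(Δy² + Δx_C² + Δz_C²) with each axis difference converted to µm
   first — mandatory given the 10:1 voxel anisotropy.
7. **Motility** per consecutive-frame pair = |Δlength| / interval;
   protraction/retraction average the pairs with increased/decreased
   length (zero-change pairs count only toward motility).  Frames where
   the process is not measurable are dropped with both adjacent pairs —
   conservative and logged — rather than interpolated.

Occupancy: per z-slice fraction of pixels above threshold, averaged over
slices, in percent.  Auto-threshold is Otsu's; the ten-images-per-stack
averaging convention is available via `min_slices=10`.

**Accuracy envelope** (established by the phantom benchmarks): straight
and in-plane-curved noiseless phantoms are recovered within 2 % (in
practice ~0.4 %); Gaussian intensity noise at SNR 5 changes recovered
lengths by < 5 %.  Centerlines that drift in z are tracked only at the
0.5 µm z_C quantization the center rule allows — for processes oblique
to the imaging plane the summed length carries a staircase bias that no
parameter fully removes at 1 µm z-steps, and the accuracy claims above
are for the in-plane regime.

## qPCR

Amplification efficiency per primer pair from a dilution standard curve:
Ct regressed on log10(relative concentration), eff = 10^(−1/slope) − 1
(perfect doubling: slope −3.3219, eff 1).  Non-monotone Cts produce a
warning carrying the fit r².

Relative amount of a target gene, corrected by both efficiencies:

    fold = (1+eff_target)^dCt_target / (1+eff_ref)^dCt_ref

with dCt = Ct_control − Ct_sample (default), so fold > 1 means higher
expression in the sample; with both efficiencies 1 this is the classic
2^−ΔΔCt.  The alternative `convention="sample-minus-control"` uses the
opposite sign in both exponents (the reciprocal) for compatibility with
reports that state the formula in that orientation; the convention in
force is always logged.  Technical replicates are averaged per
(sample, gene) before the formula.  When two candidate reference genes
are available, `choose_reference_gene` picks the one with the lower
within-group Ct variance.

## Synthetic generators

All generators derive their random stream from (seed, generator-id), so
one seed reproduces byte-identical data and adding a generator never
perturbs the others; ground truth travels in separate objects/sidecar
files, never inside the data.

* **Censuses**: apo ~ Poisson(40), engulfment ~ Binomial(p = 0.9 — the
  physiological regime where >90 % of apoptotic cells are already in
  pouches), microglia ~ Poisson(300) per 0.05 mm³ region.  *Coupled*
  challenge: apoptosis ×3 with engulfment probability unchanged, so net
  phagocytosis tracks apoptosis (expected Ph/A fold 1).  *Uncoupled*:
  apoptosis ×3 with engulfment probability dropped to 0.3.  Engulfed
  cells are assigned to microglia uniformly at random, which *is* the
  pouch histogram — capacity, net phagocytosis and Ph index are
  automatically consistent.
* **Cohorts**: homogeneous-Poisson entry into apoptosis; exponential
  clearance with mean τ; tallies of present and cumulatively cleared
  cells.  Steady-state present count = rate·τ (the Little's-law check).
* **Phantoms**: a tube whose centerline wiggles sinusoidally in x (and
  optionally z), with separable Gaussian cross-section per xz plane
  (σ_x = 0.3 µm, σ_z = 0.8 µm), sharp ends in y, rendered at the real
  acquisition geometry; white Gaussian noise at a commanded SNR.  The
  ground-truth length is the analytic polyline arc length of the
  rendered centerline.
* **Ct tables**: Ct = base − log_(1+eff)(abundance) + noise, from known
  fold changes and efficiencies.

What the phantoms do *not* emulate: branching, varying process caliber,
other fluorescent structures nearby, photobleaching, or registration
error.  Passing the phantom benchmarks shows the geometry pipeline is
correct and noise-stable, not that process selection in crowded real
stacks is automatic — selection remains manual, as in the intended use.

## Problem sizes

The bundled tests and the acceptance script use 200 samples per census
group, 10⁴-cell cohorts, 30 µm phantoms over 2–10 frames, and
6-sample/triplicate Ct tables — sizes chosen so every stochastic check
sits well inside its tolerance while the whole suite runs in seconds.
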