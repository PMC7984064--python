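# Methods

This note documents the models behind `pinclust`, the parameters that
matter, and what the synthetic-data experiments do and do not show.

## Confocal cluster detection

Membrane ROIs are axis-aligned sub-volumes with a user-declared projection
axis (the membrane normal). Automatic inference of the normal is
deliberately out of scope: in root-tip stacks the relevant membranes lie
perpendicular to the focal plane and the correct projection direction is a
property of how the ROI was drawn, not of the data.

The detector is rank-based throughout. A cluster candidate is a pixel
strictly brighter than its eight in-plane neighbours in the
maximum-intensity projection; ties produce no peak, and border pixels
(incomplete neighbourhoods) are never peaks. The size class of a peak is
the largest window radius *n* ≤ `n_cap` such that no pixel of the
(2n+1)×(2n+1) window outranks the peak, reported as `side_px = 2n+1`.
Because only intensity ranks enter, the detector is exactly invariant under
adding a constant or multiplying by a positive constant — the property that
makes it thresholding-free.

Conventions and tunables:

* **Size convention.** `side_px = 2n+1` is the default; the odd classes 5,
  7, 9 correspond to 0.445–0.801 µm at the 0.089 µm lateral pixel. An
  alternative even convention (`2n`, so the brightest pixel of a clean 9×9
  window is an "8-pixel" cluster) is available via `alt_2n_convention` for
  comparison with reports using that reading; the retained-range gate is
  defined on the odd classes.
* **Size gate.** Calls with 5 ≤ `side_px` ≤ 9 are retained. Below the gate
  the detection is dominated by noise texture; above it, large structures
  such as overlapping membrane sections take over. Both gates are
  configurable.
* **`n_cap` = 6** (side 13). Growth must terminate; anything that reaches
  the cap is already above the retained range. Calls stopped by the cap or
  by the ROI border are marked `capped` and excluded from the gate, which
  avoids biased small size classes at edges.
* **Borders.** 0-based, half-open bounds everywhere; peaks require a
  complete 3×3 neighbourhood.
* **Membrane area.** Brightness thresholding of the projection, Otsu by
  default, with an absolute override. The override is the right choice
  whenever the projected plane is entirely membrane (en-face sheet views),
  where Otsu would split the membrane itself.
* **Low-contrast flag.** A strict local maximum in flat noise acquires a
  size class purely through ranking statistics, and the probability that a
  noise maximum classifies into the 5–9 px gate is independent of the noise
  amplitude (ranks are scale-free). Flat noisy regions therefore produce
  in-gate false positives at any signal-to-noise ratio; in the original
  procedure these were discarded by eye. As a reproducible surrogate, every
  call whose 3×3 neighbourhood mean falls below a plane percentile
  (default 90) is flagged `low_contrast`. The default pipeline only flags;
  recovery analyses (and the acceptance script) enable
  `drop_low_contrast=True`, which stands in for the manual curation step.

## Immunogold linkage statistics

Particles are grouped by single linkage with an inclusive threshold:
connected components of the graph joining all pairs at centre-to-centre
distance ≤ 55 nm (`dmax` configurable). Groups of 1 / 2 / ≥3 particles are
scattered / doublets / clusters, and class fractions are percentages of
particles, the convention under which the three fractions sum to 100%.
The group diameter is the maximum pairwise centre distance (Feret style),
optionally plus a gold-label diameter; a singleton's diameter is the label
diameter alone. The partition is exactly invariant under rigid motions and
under joint rescaling of coordinates and threshold, and increasing `dmax`
can only merge groups — properties asserted in the test suite.

Polar domains follow the band construction: apical = axial distance from
the apical edge ≤ 2 µm, basal symmetric, central = a 2-µm-wide band centred
on the midline. Cells shorter than twice the band are rejected (the polar
bands would overlap); in cells where the central band touches a polar band
the apical/basal labels take precedence. Band areas are computed by
clipping the analyzed-region polygon with the band strip, so densities
remain correct for irregular analyzed regions. Thin-section (IEM) data use
the same axial assignment, with per-image cluster counts summarized as
mean ± SD (sample SD; a single image reports SD 0). A quantity sometimes
reported as "clusters with radii > 55 nm" is not computable from a linkage
threshold; this package reports counts of ≥3-particle clusters instead.

## Synthetic confocal stacks

The generator plants planar membrane sheets (slabs, default 2 voxels
thick) carrying Poisson-distributed Gaussian spots, blurs the volume with
an anisotropic PSF and adds noise. It is an *instrument model*, not an
optical simulation: its purpose is to give the detector data with known
truth under the acquisition geometry of interest.

Key defaults, with rationale:

* **Voxel size 0.089/0.089/0.313 µm (x/y/z), 16 z-slices.** The stated
  acquisition geometry; the axial PSF sigma (0.30 µm) exceeds the lateral
  one (0.11 µm), reproducing the z-elongation artifact.
* **Spot FWHM 0.65 µm.** Spots are isotropic 2D Gaussians in the sheet
  plane, extruded through the slab. After PSF convolution the apparent
  diameter is ≈ 0.70 µm, inside the detector's retained 0.44–0.80 µm class
  range — the generator emulates the structures the detector was built to
  count, and this width was fixed by calibrating the simulator against the
  detector's stopping physics before the recovery experiments were frozen.
* **Amplitude 5, additive Gaussian noise σ = 1 (SNR 5).** With a
  rank-based detector the SNR controls *where* window growth stops: at
  high SNR nothing in flat background can ever outrank a peak, so isolated
  spots run to the cap and are excluded; at SNR ≈ 5 the noise stops growth
  on the spot flank, where the profile has dropped by a few σ. SNR 5 is
  therefore the regime in which apparent size classes track spot geometry.
* **Determinism.** One `numpy` Generator per simulation call, seed
  mandatory; identical parameters and seed give bit-identical stacks and
  truth.

Spots with FWHM below one lateral voxel are rejected as undetectable.

What the stack generator does *not* emulate: membrane curvature and
folding, intra-membrane background texture from unclustered protein,
uneven illumination, and detector-correlated noise. Passing recovery tests
show the pipeline is unbiased under the generative model at the planted
densities; they do not certify absolute densities on real membranes, where
the manual-curation surrogate and the area threshold matter most.

## Synthetic immunogold fields

Labels follow a Thomas-type cluster process on a rectangular sheet
(default 10 µm × 10 µm, apical edge at y = 0): Poisson parents — optionally
thinned by an exponential gradient `exp(−d_apical/decay)` — each emit
Poisson-many labels with isotropic Gaussian scatter (σ = 15 nm), plus
homogeneous scattered singles. Parents are sampled with a 3σ margin around
the field (plus-sampling) so edge clusters are not depleted. Each label is
then displaced uniformly within a 20-nm disc (the epitope-to-gold
distance), retained with the labeling efficiency (default 0.8), and
clipped to the field.

Truth classes are *configuration truth*: the 55-nm linkage applied to the
complete, undisplaced, unthinned label configuration. There is no latent
cluster identity beyond the distance rule, so recovery experiments measure
exactly what displacement, thinning and clipping do to the observed
fractions.

Two presets pin the study conditions:

* **Polar marker** (strongly clustered): parents 0.35 µm⁻², mean
  occupancy 6, scattered 1.65 µm⁻² → ≈ 55% of labels in clusters. The
  occupancy of 6 reflects the large polar-domain clusters seen in replica
  labeling and keeps thinned clusters above the 3-particle definition: a
  Binomial(6, 0.8) survivor count rarely drops below 3, so the recovered
  clustered fraction stays within a few points of configuration truth.
* **Nonpolar marker** (mostly scattered): parents 0.03 µm⁻², occupancy 3,
  scattered 2.3 µm⁻² → ≈ 3% clustered at ≈ 2.4 labels/µm².

Both presets were calibrated analytically (Poisson-mixture expectation of
the clustered share) before the recovery tolerances were frozen. The field
generator does not emulate fracture-face occlusion, antibody geometry
beyond the displacement disc, or label–label exclusion.

## Polarity index

Mean (not integrated) intensity per ROI, background subtraction optional
and off by default — with both conventions unspecified in common practice,
the mean-based ratio is the choice invariant to ROI size. Ratios are
computed per cell, then averaged across cells.

## Statistics

Tests are two-sided. The Mann–Whitney U uses the exact null when both
groups have at most 8 observations and the pooled data are tie-free,
otherwise the mid-rank normal approximation (the two agree within 0.02 by
n = 20, asserted in the tests). Two degenerate t-test inputs are handled
by convention and flagged: zero variance in both samples gives p = 1 for
equal means and p = 0 otherwise. Star thresholds are configurable and
echoed in the output rather than hard-coded, since legend conventions
vary; no multiple-testing correction is applied.

## Problem sizes

The recovery experiments use 192×192×16 stacks (≈ 292 µm² of membrane,
10 seeds per density level) and 100-µm² fields (20 seeds per preset);
oracle-equivalence suites run 100 random planes (≤ 32×32) and 100 point
sets (≤ 300 points) against brute-force enumeration. These sizes give
standard errors comfortably inside the stated tolerances while keeping the
whole suite fast on one CPU.

## Known limitations

* Confocal absolute densities depend on the low-contrast curation
  surrogate; on data with strong membrane texture the percentile flag is a
  blunter instrument than manual review.
* The growing-window size class measures distance-to-brighter-structure,
  not spot FWHM; size histograms from the detector should be read as
  ordinal classes, not calibrated diameters.
* Domain band densities assume a straight apical–basal axis; strongly
  curved cells would need a curvilinear axis, which is not implemented.
* The 55-nm linkage is a hard threshold: fractions respond sharply to
  coordinate calibration errors near the threshold. The joint-rescaling
  invariance test shows how to keep analyses consistent across
  magnifications.
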