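# Methods

This note documents the models behind `ishquant`, the defaults and why they
were chosen, the numerical decisions, and what the synthetic validation
does and does not establish about real data.

## The quantification model

The measurement unit is the **cell mask**: each DAPI-segmented nucleus is
expanded into a surrogate whole-cell region of exactly twice the nuclear
area, standing in for soma plus proximal cytoplasm when no membrane stain
is available. Per transcript channel, the per-cell **expression score** is

    score = (number of dots whose centroid lies in the mask) / mask area,

reported both as the raw ratio (dots/px²) and as a physical density
(dots per 100 µm²). "Dot signal" is interpreted as dot *count*: in
single-molecule ISH each dot is approximately one transcript, and counting
is robust to illumination differences. An intensity-sum reading
(`{channel}_intensity_sum`, the sum of detected peak intensities per cell)
is emitted alongside for users who prefer it; it is not the tested default.

Cells are **typed** by marker channels: a rule fires when the marker's dot
count in the mask reaches its threshold (default ≥ 3 dots, a conventional
single-molecule-ISH positivity floor; configurable, including a density
variant). Cells firing no rule are `untyped`; cells firing several are
resolved by highest marker dot density (an `exclusive` policy that marks
them `ambiguous` instead is available). Target **positivity** is ≥ 1 target
dot by default; because this threshold is a judgement call, the run
manifest always reports percent positive at min_dots ∈ {1, 2, 3}.

Population comparison pools cells across sections for the score histogram
(left-closed bins of width 1 from 0) and the two-sided Wilcoxon rank-sum
test; percent positive instead treats the *section* as the data point
(per-section percentage, mean ± SEM across sections), matching how such
studies report replicate variability. No multiple-testing correction is
applied across regions by default (each region is reported on its own);
`adjust_pvalues` provides Bonferroni and Benjamini–Hochberg when a user
compares many regions.

## Mask expansion: an area budget, not a dilation radius

"Twice the nuclear area" is enforced per cell. All background pixels within
a per-label cap are candidate claims, ordered by exact integer squared
Euclidean distance to the nearest pixel of that nucleus; claims are granted
in increasing (d², label id, row, col) order while the label's area is
below `expansion_factor × nucleus_area`. Consequences:

- isolated nuclei end within one pixel-ring of exactly 2× area (the
  residual is pure discretisation; the suite checks |ratio/2 − 1| ≤ 5%);
- contested pixels go to the nearer nucleus, so masks are disjoint by
  construction and growth stops at equidistant frontiers;
- crowded or edge cells may end below budget; the per-cell
  `achieved_expansion` and `edge_cell` columns expose this so downstream
  analysis can filter (edge cells are kept by default, droppable by flag);
- the deterministic claim order makes the operation reproducible bit for
  bit and lets an exhaustive per-pixel oracle reproduce it exactly (the
  test suite does, on a battery of ≤ 64×64 fields).

The per-label growth cap is `sqrt(expansion_factor) · r_eq + 3 px`
(r_eq the equivalent-disk radius): enough slack for a partially blocked
label to reach its budget without scanning the whole field.

## Spot detection

Multiscale Laplacian of Gaussian: the response `−σ²·∇²(G_σ ∗ I)` is
computed at `n_scales` geometrically spaced σ in [sigma_min, sigma_max]
(default 0.9–1.8 px, bracketing the rendered PSF), maximised over scale,
and peaks are kept by non-maximum suppression (min separation 1 px) above
threshold, with sub-pixel refinement by a 1D quadratic fit per axis
(clipped to ±0.5 px). Two thresholding modes:

- **auto** (default): each scale's response is centred and divided by its
  robust noise level (1.4826 × MAD), so the threshold is in matched-filter
  SNR units (default 5σ). This adapts to the channel's noise floor; on a
  (near-)noise-free image it falls back to 5% of the peak response.
- **absolute**: a fixed cutoff on the scale-normalised response (for a
  Gaussian dot of amplitude A at matched scale the response peaks at ~A/2).

No declumping is attempted: puncta closer than ~2σ merge into one detected
spot. This is the dominant error source in dense cells and the reason
counts saturate at high expression (see Limitations).

## Rank-sum test

Midranks handle ties. For n₁+n₂ ≤ `exact_limit` (default 16) the null
distribution of the rank sum W is enumerated over all C(n₁+n₂, n₁)
assignments of the observed midranks, and
p = min(1, 2·min(P(W ≤ w), P(W ≥ w))) — exact even under ties, because the
enumeration permutes the midranks actually observed. Larger samples use
the normal approximation with the standard tie-corrected variance and a
0.5 continuity correction. The suite verifies the exact branch against
independent brute-force enumeration and scipy's exact distribution, the
approximate branch against scipy and against the exact p at n=50, and the
empirical type-I error at α = 0.05 (within [0.035, 0.065] over 1000 null
simulations).

## The synthetic-field generator

The generator emulates the imaging regime of a multiplex fluorescent ISH
study of mouse brain sections: a DAPI channel plus up to three transcript
channels, grouped by animal → section → image (default study: one animal,
4 sections, 3 images per section — four sections per animal with 2–4
images per section being the usual sampling design).

Per image (defaults in parentheses):

- nuclei: n_cells (50) placed by rejection sampling at pairwise centre
  separation ≥ min_nucleus_separation_px (16), radius ~ N(3.0, 0.3) µm,
  rendered as soft-edged blobs (logistic falloff, edge 0.8 px);
- cell types from `type_proportions` (glutamatergic/GABAergic at 0.5/0.5);
- per-cell counts per channel from a negative binomial (mean m, dispersion
  k; variance m + m²/k) or Poisson. Defaults: target *Gprc5b* NB(3, 2) in
  glutamatergic vs NB(8, 2) in GABAergic cells (heavy-tailed counts with a
  clear population contrast whose closed-form positive fractions are 84%
  and 96%); own marker NB(20, 5), cross marker Poisson(0.1). The true
  count distribution of such data is unknown — the NB family is a
  configurable assumption, with Poisson as its dispersion→∞ limit;
- dots uniform in the disk of radius sqrt(expansion_factor)·r around the
  owner's centroid — exactly the region the mask expansion reconstructs —
  rendered as isotropic Gaussians (σ 1.1 px, amplitude 150) plus optional
  uniform stray dots (rate per mm², default 0, exercising the unassigned
  path);
- optional linear channel bleed-through on the clean signal, then additive
  background (20) and Gaussian read noise (sd 15; SNR = amplitude/noise_sd
  = 10 by default), clipped at 0. Shot noise, autofluorescence texture,
  photobleaching, 3D structure and stitching are deliberately out of scope;
- geometry: 0-based (row, col), pixel centres at integers, default
  288×288 px at 0.5 µm/px; placement margins keep every cell's dot disk
  inside the field;
- randomness: one integer seed expands via `SeedSequence.spawn` into
  per-stage substreams (placement, radii, types, counts, dots, stray,
  noise), so adding a stage never perturbs earlier draws and identical
  (config, seed) gives byte-identical images, tables and summaries.

### Problem sizes and imaging regimes used in validation

The default 0.5 µm/px sampling keeps a full 12-image study around two
seconds, which is what makes replicate-level validation (100 pipeline
replicates for the population-contrast check) practical; at that sampling,
however, puncta in high-count cells overlap heavily and merge. Marker-based
typing is therefore validated in the assay's proper operating regime —
0.25 µm/px, PSF σ 1.2 px ≈ 0.3 µm, 30 cells per 448×448 field, own marker
NB(15, 10), cross marker Poisson(0.1) — where puncta are resolvable, which
is precisely the regime in which dot-count typing is a valid method
(measured accuracy ≈ 99.6%; the irreducible remainder is cells whose true
own-marker count falls below the 3-dot threshold). Detection quality is
scored on uniform dot fields at SNR 5 and 0.02 dots/µm², inside the sparse
regime where single-molecule counting is meaningful.

## What passing tests do and do not show

The synthetic validation establishes that the pipeline's geometry,
accounting and statistics are correct: masks meet the 2× contract, spot
assignment conserves counts exactly, injected ground-truth dots are
recovered per cell, the rank-sum implementation is exact, and the full
pipeline recovers a known population contrast in direction, significance
and percent positive. It does **not** establish performance on real
tissue: real sections add autofluorescence, section-thickness and z-stack
effects, nuclear segmentation errors in dense neuropil, probe efficiency
differences and transcript clustering that the generator does not model.
Absolute per-cell counts in high-expressing cells should be treated as
lower bounds (clump merging), which is also why the population comparison
uses ranks rather than means.

## Other numerical decisions

- Otsu thresholding on the smoothed DAPI image (fixed threshold available);
  flat images yield an empty label map, not an error. Objects below
  min_nucleus_area_px (40 px) are removed before and after the watershed
  split; watershed seeds are distance-transform peaks ≥ min_seed_distance_px
  (8 px) apart.
- Spot-to-cell assignment is centroid containment (rounded pixel), matching
  the single-pixel semantics of a punctum; a dot just outside an achieved
  mask is unassigned, and the recovery tests account dots outside masks
  explicitly.
- Percent-positive SEM uses ddof=1 across sections; a single section
  reports SEM 0.
- The histogram's binned variable is the density score (dots per 100 µm²)
  by default; raw counts are available (`score_mode="count"`). The unit of
  published "expression amount" axes is typically unstated, so both modes
  exist and neither is asserted as canonical.
- Cells from all animals/sections are pooled before the rank-sum test
  (hierarchical modelling of the animal level is out of scope).
- 16-bit label TIFFs cap a field at 65535 cells; CSV tables carry a schema
  version header (`ishquant.cell_table.v1`).

## Known limitations

- No declumping: counts saturate in dense cells; at coarse sampling this
  also limits typing accuracy (see the imaging-regimes section).
- The 2×-area mask is a convention, not a measured cytoplasm; scores are
  comparable across cells and populations, not absolute concentrations.
- Nearest-centroid matching in the validation harness can mismatch when
  segmentation merges adjacent nuclei; the watershed split makes this rare
  at the default densities.
- The generator's noise is Gaussian-additive only; detector gain and shot
  noise are not modelled.
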