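# Methods

## The detection model

The pipeline treats microbleed detection as dark-blob detection under two
complementary views of the same volume. The 3D radial symmetry transform
scores how strongly intensity gradients in a voxel's neighbourhood converge
on it at a set of physical radii; a hypointense sphere produces a tight
cluster of coincident votes at its centre, while edges, sheets and tubes
scatter their votes along lines or planes. The second stage exploits
projection geometry: across a 12-mm minimum intensity projection a sphere's
silhouette stays a compact disc, whereas a vessel that traverses the slab at
any appreciable obliquity smears into a streak, so re-scoring the projected
patch with the 2D transform separates the two even when their 3D responses
are similar. Both stages are pure threshold operations on per-location
scores, which is what makes the exhaustive threshold lattice cheap: the 3D
map is computed once per participant, 2D scores are memoized per peak voxel,
and every lattice point is evaluated by re-thresholding — provably identical
to re-running the pipeline at that setting.

Key modelling assumptions:

- Lesions are approximately spherical and darker than surrounding
  parenchyma; detection polarity is fixed to dark.
- The in-mask intensity histogram has a genuinely dark bottom tail (CSF
  spaces, sulci, vessels) below normal tissue, so the 6th-percentile floor
  of the normalization sits well below parenchyma and lesion contrast
  survives clipping.
- Voxel spacing metadata is trustworthy; all radii, slab thicknesses and
  matching tolerances are physical (mm), never voxel counts.

## Transform details and numerical choices

- **Gradients** are central differences divided by per-axis spacing
  (one-sided at boundaries), giving intensity/mm on any grid.
- **Vote geometry.** The vote offset is rounded per axis after dividing the
  physical step `n·ĝ` by the axis spacing. Anisotropy is handled in vote
  geometry rather than by resampling, avoiding interpolation artifacts at
  3-mm slice thickness. Votes that leave the grid are discarded.
- **Saturation count `k_n`** is `min(shell_vote_count(n, spacing), 10)`,
  where `shell_vote_count` counts the voxel offsets from which a perfectly
  radial unit gradient votes exactly onto the centre (computed once per
  radius/spacing pair, floored at 1). The cap matters: with a full
  shell-sized `k_n`, the strictness exponent `α = 2` punishes the inevitable
  vote dispersion of large radii (gradient-direction noise plus per-axis
  rounding) roughly as dispersion³, suppressing 8–10-mm lesions an order of
  magnitude below 2-mm ones. A small constant cap lets any blob with ~10
  coincident votes saturate the orientation term regardless of its size,
  which is also how the transform's original 2D formulation normalizes.
- **Response scale.** Magnitudes enter in intensity/mm on the [0, 255]
  normalized volume. With the defaults this puts typical phantom lesion
  peaks at roughly 3–20 and the useful operating band across 0.5–3.0,
  which is the lattice the evaluation sweeps.
- **Stage-1 reduction** takes local maxima of the map (26-neighbourhood by
  default; plateau ties resolve to the lexicographically smallest voxel)
  above `T3D` inside the mask, rather than one peak per connected
  suprathreshold component. The local-max set of a fixed map is independent
  of the threshold, so candidate counts and sensitivity are monotone in
  `T3D` by construction and cached threshold sweeps are exact. Per-component
  reduction lacks both properties: sheet-like structures merge into one
  component at low thresholds and split into many at high ones.
- **Degenerate inputs.** A constant volume has no gradients and maps to
  zero everywhere. A constant in-mask histogram raises a degenerate-
  histogram error rather than dividing by zero. Radii too small for the
  grid to resolve produce self-votes and a flat response instead of
  failing. Out-of-mask voxels are filled with 255 (bright) before the
  transform so the mask boundary does not imitate a dark blob; mask corners
  still produce edge artifacts, which stage 2 must reject like any other
  false positive.
- **Stage-2 readout** takes the maximum 2D symmetry value within a 1-voxel
  halo of the patch centre, absorbing the voxel-scale offset between the
  stage-1 peak and the minIP peak. The slab selects slices whose centres
  lie within ±6 mm of the candidate's slice (five slices at 3-mm spacing,
  fewer at volume edges), and the pass rule is strict: a candidate survives
  only if its 2D value exceeds `T2D`.
- **Matching** between candidates and reference lesions is greedy
  one-to-one in ascending Euclidean world distance with a 5-mm tolerance
  (about half the largest common microbleed diameter and more than one
  slice thickness); ties break deterministically on indices. Sensitivity
  pools true positives over the cohort; the FROC x-axis is mean candidates
  per participant (true positives included), matching how such screening
  workloads are reported.
- **Frontier rule:** a lattice point survives unless another point has at
  least its sensitivity and at most its candidate burden with one strict
  inequality; exact ties on both axes keep the stricter (larger)
  threshold pair.

## Default parameters

| Parameter | Default | Units | Why |
| --- | --- | --- | --- |
| Normalization percentiles | 6 / 95 | — | dark lesions fall below the 6th percentile; output clipped to [0, 255] |
| Radii `n` | 1, 2, 3, 4, 5 | mm | covers lesion radii for diameters ~2–10 mm |
| Strictness `α` | 2 | — | quadratic punishment of incomplete vote rings suppresses elongated structures |
| Smoothing | 0.5·n | mm | consolidates the dispersed vote cluster at scale proportional to the radius |
| Gradient cutoff | 0.2·max | — | keeps lesion rims voting, silences acquisition-noise gradients that otherwise flood stage 1 |
| `k` saturation | 10 | votes | size-uniform saturation of the orientation term (see above) |
| minIP slab / ROI half-width / halo | 12 / 12 / 1 | mm / mm / voxels | slab per the screening protocol; ROI comfortably contains the largest radius plus smoothing support |
| Match tolerance | 5 | mm | physical, grid-independent association of marks with lesions |
| Presets A / B / C | (3.0, 2.0) / (3.0, 1.0) / (0.5, 0.5) | — | moderate/good/high-sensitivity points on the standard phantom cohort's frontier; site-calibrated, re-derive on real data |

## The phantom generator

`standard_cohort` emulates the statistical structure of a memory-clinic
T2\* study at desk scale: 96×96×40 grids at (1, 1, 3) mm, about 53% of
participants with at least one lesion, right-skewed per-participant counts
(1 plus a geometric tail), diameters uniform on [2, 10] mm, fractional
intensity depths uniform on [0.5, 0.9], 3–8 vessel-like tubes and 1–2
fissure-like planes per participant as decoys. The background superimposes
mild smooth anatomical variation (sd 12 at 20-mm scale), a dark-structure
compartment (the negative tail of an 8-mm-scale random field, darkening up
to 60%) that occupies roughly the bottom decile of the histogram the way
CSF spaces and sulci do, and additive Gaussian noise (sd 8 on a background
of 200). Lesions darken multiplicatively with an error-function edge about
one voxel wide — hard edges would make gradient voting unrealistically
easy — and compose by taking the darkest factor where they overlap.
Spheres are placed in parenchyma (outside the dark-structure tail, as real
microbleeds are rated in tissue); tubes drift 30–60 mm in-plane across the
stack so a 12-mm projection elongates them, and keep a 10-mm in-plane
standoff from lesion centres so decoys do not corrupt lesion patches.

What the phantoms deliberately do **not** model: real anatomy (the mask is
an eroded box, so mask-corner artifacts stand in for skull-base artifacts),
susceptibility physics and blooming beyond a smooth edge profile,
calcifications, motion artifacts, multi-echo information, and vessels
running exactly perpendicular to the slices — a perpendicular vessel stays
a compact disc in any transversal minIP and is indistinguishable from a
sphere by this method's own premise. Passing the phantom suite therefore
demonstrates the pipeline's geometric and statistical machinery, not
clinical performance; sensitivities on real scans depend on contrast,
artifacts and rating conventions the phantoms cannot capture.

## Problem sizes used by the tests and the acceptance script

The packaged evaluation runs a 20-participant standard cohort (seeded), a
full 42-point lattice with cached scoring, and transform-versus-oracle
equivalence on twenty random 16³–24³ volumes; these sizes exercise every
code path while keeping the whole suite around a minute on one CPU.

## Known limitations

- Stage-2 scores are computed on demand per candidate, so wall time grows
  with the stage-1 candidate count at the most permissive threshold in use.
- The transform's response still decays mildly with lesion radius even
  with the capped saturation count; lesions larger than the largest voting
  radius are under-scored (configure `radii_mm` for different lesion
  populations).
- Threshold presets are data-dependent. The shipped A/B/C values are
  calibrated on the phantom cohort and must be re-derived per site or
  protocol from a FROC sweep on rated data.
- The matching rule is a geometric stand-in for visual confirmation; a
  5-mm tolerance can in principle pair a candidate with a neighbouring
  lesion in dense clusters.
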