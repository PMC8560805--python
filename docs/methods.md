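# Methods

## The assay

Serum-starved fibroblasts are stained for nuclear material (DAPI), the
ciliary axoneme (acetylated-α-tubulin), the ciliary membrane (ARL13B),
the basal body (pericentrin) and intraflagellar transport protein
IFT88.  From 2D fields of such cells the package measures, per cell
line:

- **ciliogenesis** — the percentage of cells carrying an extended
  axoneme, with the remainder split into "spot" (round, non-extended
  axoneme) and unciliated cells;
- **cilium length** — per-cilium, in µm, summarized as a bootstrap
  median because per-cilium lengths are not normally distributed;
- **IFT88 area** — µm² of accumulated IFT88 signal per cilium, a
  fixed-cell surrogate for defective retrograde (tip-to-base) IFT,
  likewise summarized as a bootstrap median.

Everything downstream works in physical units (µm, µm²); the pixel
grid (0-based, row/col, origin top-left) never leaks past the
detection layer.

## Detection chain

**Nuclei.** Rolling-ball background subtraction (radius 50 px,
computed on a 4×-downscaled copy since the background varies on a
coarse scale) → global Otsu → hole filling → removal of objects below
20 µm² → distance-transform watershed with seed maxima at least 4 µm
apart to split touching nuclei.  Border-touching nuclei are kept: the
ciliogenesis denominator should not shrink at field edges.

**Channel merge.** Each ciliary channel is contrast-normalized by a
percentile 1–99.9 rescale to [0, 1], then merged by pixel-wise
maximum.  Staining gaps rarely coincide between the tubulin and ARL13B
channels, so the merged signal is continuous where either single
channel would fragment — this is the property that makes automated
length measurement reliable, and the synthetic generator reproduces it
explicitly (gaps are never painted at the same arc position in both
channels).

**Cilium candidates.** Otsu threshold on the merged raster →
morphological closing (disk, 2 px) to bridge residual sub-gaps →
connected components.  Components below 0.15 µm² are noise; components
touching the field border are discarded because their length would be
truncated (lengths must be unbiased even though this slightly reduces
the cilium count; the assignment stage, not the candidate count,
drives ciliogenesis).  Each candidate carries the longest geodesic
path through its morphological skeleton.

**Basal bodies.** Laplacian-of-Gaussian blob detection (σ 1–3 px,
scale-normalized response threshold 0.1) with intensity-weighted
sub-pixel refinement in a 5×5 window.

**Assignment.** A candidate is anchored to the nearest basal-body
punctum within 1 µm of either skeleton endpoint.  Each candidate goes
to the nucleus with the smallest boundary-to-base distance (≤ 15 µm);
a contested nucleus keeps the largest candidate and the rest stay
unassigned — primary-cilium biology admits one cilium per cell.  The
detection constants (20 µm², 0.15 µm², 1 µm, 15 µm, …) are not
prescribed by the assay itself; they are package defaults justified by
fibroblast geometry, all overridable through the run configuration.

## Length estimation and calibration

Skeleton length is the weighted diameter of the skeleton's pixel
adjacency graph: 4-neighbor steps count 1, diagonal steps √2, side
branches shorter than 3 px are pruned first (an endpoint whose path
reaches no junction within 3 px is a true cilium end and is kept).
This raw estimate carries two systematic errors: the skeleton retracts
by roughly the tube radius at each end (underestimate) and diagonal
stepping over a digitized curve overestimates arc length by a few
percent, orientation-dependently.  Both are absorbed by an affine
calibration `true = slope·raw + offset` fitted by ordinary least
squares on an *artificial dataset*: rendered fields of fully ciliated
cells with known arc lengths uniform in 1.5–5.5 µm, staining gaps
enabled.  Typical fits give slope ≈ 0.93, offset ≈ +0.12 µm with
residual scatter of ~2–4% — measured, like every number in this note,
by the validation battery itself.  The pipeline reports lengths as
calibrated only when an explicit calibration is supplied; otherwise
`length_um` equals the raw skeleton length and the CLI says so.

## Structure classification

A candidate whose corrected length is below 1.0 µm **and** whose
circularity `4πA/P²` exceeds 0.6 is a "spot"; everything else is a
cilium; cells without an assigned candidate are "none".  The two
thresholds operationalize a qualitative morphological distinction
(round, non-extended staining) and are configuration constants.
Circularity is computed on the post-closing mask, which rounds very
small shapes; the 0.6 value was chosen with that in mind.

## IFT88 quantification

The search region is the candidate mask dilated by 3 px.  IFT88
intensities *within the region* are thresholded by Otsu, so each
cilium gets its own threshold separating accumulations from the faint
axonemal IFT background, and the area is the above-threshold pixel
count × pixel area.  A region without dynamic range (max−min < 1e-6)
measures 0.  All accumulations along the axoneme count by default;
`tip_only=True` restricts the region to within 1 µm of the distal
skeleton endpoint to emulate manual tip-only scoring, which is how the
two conventions are compared (after normalizing each to the mean of
the control lines, since their absolute scales differ).

## Summaries

Ciliogenesis percentages are pooled over all cells of a line; the
quoted SD is across per-field percentages.  Medians are plain sample
medians; their SD comes from 10 000 full-size bootstrap resamples
(seeded, default 20210527).  The point estimate is deliberately
resampling-free: seed and resample count affect only the SD.  Cilia
with zero measured IFT area (no transport plane, or no accumulation)
are excluded from the IFT median.  Group-level rows can be computed
two ways — mean of per-line values (default) and pooled-cilia
bootstrap median — because no single rule reproduces published group
rows from per-line rows; both are exposed.

## Cohort model

Per group (control, ATD, CED), the model is the mean and 2×2 sample
covariance of per-line (length, IFT) medians; the confidence region at
level q is the ellipse `(x−μ)ᵀΣ⁻¹(x−μ) ≤ χ²₂(q)` with χ²₂(0.5) = 1.386
and χ²₂(0.9) = 4.605.  Ellipses are fit on per-line medians (one dot
per individual), not pooled per-cilium values.  Assignment is by
minimal Mahalanobis distance — the two axes have different units and
group spreads, so Euclidean distance would be meaningless — with exact
ties broken in the order control, ATD, CED and flagged.  A group needs
at least 3 lines; during leave-one-out evaluation a held-out group may
drop to 2, in which case its covariance falls back to the pooled
within-group covariance (every covariance also gets +1e-9·I).  A point
outside all 0.9 ellipses still gets a nearest-group label but is
surfaced as unclassifiable at the 0.9 level.

## Synthetic fields

The generator emulates the assay's geometry, not its optics:

- **Nuclei**: non-overlapping ellipses, semi-axes 4.6–5.4 × 3.8–4.6 µm
  (modest eccentricity keeps one distance-transform maximum per
  nucleus).  Placement is dart-throwing with restarts; impossible
  packings raise an error.
- **Cilia**: quadratic Bézier tubes of width 0.25 µm
  (diffraction-limited axoneme) whose apex height is capped so
  chord/arc ≥ 0.85 — gently bent, never self-overlapping.  The painted
  arc length matches the requested length to well under one sub-pixel
  step (dense polyline construction).  Per-channel staining gaps
  (default probability 0.5, length 0.5 µm) are placed so the
  two-channel union stays continuous.
- **Basal bodies**: Gaussian puncta (σ 1.2 px) at cilium bases.
- **IFT88**: a faint axonemal background (0.25 of peak) along the tube
  plus a disk of the requested area centred one disk-radius back from
  the distal tip, keeping it on the axoneme.
- **Spots**: sub-micron disks (0.6–0.9 µm diameter) positive in the
  axonemal, membrane and basal-body channels.
- **Optics/noise**: per-plane Gaussian blur (default σ 0.1 µm),
  optional Poisson shot noise, additive Gaussian noise (default
  σ 0.02), clipped to [0, 1].  Default sampling 0.1 µm/px on a 512×512
  field, ~12 cells per field.
- **Class mixture**: per-field counts use randomized rounding of the
  fractional remainder, so a line's expected ciliated fraction equals
  the requested one exactly while across-field variance stays far
  below per-cell Bernoulli sampling.
- Default per-cilium distributions are healthy-like: lengths
  normal(3.71, 0.55) µm (within-line spread chosen to match broad
  violin-style length distributions), tip areas normal(0.43, 0.06) µm².

One integer seed drives everything; identical seeds give bit-identical
fields.  Ground truth records every painted quantity, so noise-free,
gap-free renders are an exact oracle: the acceptance battery requires
detection counts to equal truth exactly on 20 such fields.

What the generator does **not** reproduce: real point-spread functions
(no Airy/vectorial PSF), uneven illumination, overlapping or apoptotic
nuclei, cytoplasmic background staining, out-of-focus cilia, and
cilia pointing in z.  Passing the synthetic battery therefore
demonstrates correctness of the measurement chain under the stated
geometry, not robustness to every imaging pathology; the two known
real-data failure modes (very large axonemal gaps combined with weak
proximal staining) surface through the QC flag for candidates whose
pre-closing signal was fragmented.

## Validation battery and problem sizes

`scripts/acceptance.py` (seeded end to end) recomputes: the group
means of the packaged published per-line ciliogenesis table; calibrated
length recovery on ≥150 noisy, gapped cilia (median |relative error|,
typically ~2–3%, required < 5%); exact counting on 20 noise-free
fields; ciliogenesis recovery on ~500 cells (±2 points); IFT88 medians
at healthy-like (0.43 µm²) and CED-like (0.82 µm²) settings over 10
replicates (each within 15%, CED > healthy in every replicate);
Bland–Altman coverage of Normal differences at n = 200 (≈95.4%); the
bootstrap-median SD against a fresh-sample brute-force oracle (within
15%); and cohort ellipse separation plus leave-one-out recovery on 20
simulated cohorts (6/5/3 lines at the published centroids and printed
group SDs; ATD/CED 0.9 ellipses must never overlap and ≥13/14 lines
must be recovered per cohort).  These sizes keep the full battery at a
few minutes on one CPU while leaving the statistical checks
well-powered.

## Known limitations

- The affine length calibration is fitted on this generator's geometry;
  a laboratory applying the tool to real images should refit it on its
  own calibration standard.
- Per-cilium IFT thresholding assumes accumulations are brighter than
  the axonemal background within each cilium; globally dim cilia yield
  area 0 and are excluded from the IFT median rather than imputed.
- The cohort model is bivariate normal per group; with 3-line groups
  the covariance is barely estimable and the ellipses should be read
  as illustrative.  Cluster assignment reports distances to all groups
  rather than a probability.
- 2D fields only; no z-stacks, no projection logic, no registration.
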