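# Methods

This note records the models and estimators behind each `mitoquant`
module, the defaults and the reasoning for them, what the synthetic
generators emulate (and what they do not), and the numerical choices made
where the underlying laboratory protocols leave the design open. It
states no empirical result that the test suite does not itself compute.

## Pre-processing (`preprocess`)

Images pass through a fixed chain before any morphometric measurement:
cell-ROI clearing → z maximum projection → rolling-ball background
subtraction → saturated contrast stretch → median filter → unsharp mask →
Sato (Hessian-eigenvalue) tubeness. The source workflow lists these
stages without pinning an order for contrast versus background
correction; background subtraction is applied first here, since
stretching before flattening the background would amplify it. Defaults
mirror customary FiJi values — rolling-ball radius 50 px, 0.35 %
saturated pixels (split evenly between tails), median radius 1 px,
unsharp radius 1 px / weight 0.6, tubeness scale 1.5 px — and every stage
is individually configurable or skippable; the exact settings used are
serialised into the run log because none of them are dictated by the
protocol. Binarisation is Otsu by default with a fixed-threshold
override; a constant image, which has no Otsu threshold, yields an empty
mask and a warning rather than an arbitrary split. Connectivity is
8-connected in 2-D everywhere; coordinates are 0-based (row, col).

## Network morphometrics (`morphology`)

**Branch summary.** The binary mask is skeletonised; skeleton pixels with
≥3 skeleton neighbours are junction pixels (adjacent junction pixels
merge into one junction cluster), pixels with ≤1 neighbour are endpoints,
and branches are the connected components of the remaining pixels.
Because any pixel with three or more in-component neighbours would itself
be a junction, branch components are guaranteed paths or cycles; branch
length is the terminal-to-terminal geodesic (diagonal steps √2), and a
cycle reports the total weight of its edges. A skeleton with at most one
branch counts as an *individual* (punctum or simple rod), one with more
as a *network*; `branches_per_network` averages over networks only.
Spur branches shorter than 3 px that attach to a junction are pruned
before summarisation to suppress digitisation artefacts, with a
re-thinning pass after each removal so that the attachment pixel does not
linger as a spurious junction (`prune_len=0` disables pruning, and the
oracle tests compare unpruned summaries against exhaustive path
enumeration).

**Shape.** Circularity is `4π·area/perimeter²`. The perimeter estimator
is the weighted boundary-step rule (skimage `perimeter`) rather than a
raw pixel count: on a rasterised disc of radius 30 px it yields
circularity ≈ 0.92 (raw counting overshoots the perimeter and drives
circularity far from 1), while on growing squares it converges to the
analytic π/4. The Crofton estimator was rejected because, although even
better on discs, it converges to ≈ 0.88 instead of π/4 on squares.

**Width.** The protocol measures each organelle "across the short axis"
five times and averages (the original phrasing references cristae, which
binary masks do not resolve; the short-axis reading is the only
measurable interpretation). Here `n_profiles` points are sampled evenly
along the organelle's skeleton, ordered by geodesic distance from one
end, and the local diameter at each is `2 × EDT` (Euclidean distance
transform of the object). For tubes whose centreline sits at sub-pixel
positions — the generic case — the covered pixel span is even and the
estimate is exact; a centreline exactly on a pixel centre reads one pixel
high (a 1-px line reports 2 px, the digitisation floor). Objects with
fewer skeleton pixels than requested profiles use all available points
and are flagged. Perpendicular-profile fitting was considered and
rejected as over-engineering relative to the manual ruler measurements it
replaces.

## Surface-association scoring (`association`)

Per organelle, the trapping-substrate channel is averaged over a 4-px
exterior **strip** at the organelle edge and over a 10–14-px background
**annulus**; `corrected = strip_mean − bg_mean`. Distances are EDT values
over the object-free region, so both bands exclude every object pixel.
The protocol states the band widths without inclusivity; the strip is
pinned half-open `(0, 4]` and the annulus closed `[10, 14]`.

Pixels are attributed to their nearest object, with one refinement:
pixels within a 2-px margin of the boundary between two objects'
nearest-object territories are excluded from both bands. At optical
resolution such pixels cannot be attributed to either organelle, and
plain nearest-object assignment lets a neighbour's PSF-blurred enveloping
signal bleed into an unenveloped organelle's strip — measured on phantoms
as a systematic +0.03 to +0.065 bias in the recovered enveloped fraction
at realistic densities. The margin matches the ~2 px over which a
σ = 1 px PSF spreads an edge; `exclusion_margin=0` restores plain nearest
assignment. Exact-tie pixels (equidistant between objects) are resolved
by the EDT feature transform, which is deterministic but not
lowest-label; a per-object EDT would be needed for a documented
tie order and is not worth O(n_objects × image).

Organelles whose strip or annulus is empty (image border, extreme
crowding) are flagged and excluded from the per-cell fraction. The
association threshold is not stated by the protocol; the default rule is
`mean + k·SD` (k = 2) of corrected values from no-trap control
organelles, with `k` configurable and a fixed threshold accepted
anywhere a threshold is taken. The background subtraction makes every
corrected value exactly invariant to additive offsets in channel 2.

## Mixing colocalization (`colocalization`)

Per cell, the green and red channels are summed and globally thresholded
(Otsu by default — the protocol says only "global threshold" — with a
fixed override); the mask is the pixels above threshold. The Pearson
correlation of the two channels over mask pixels is the mixing score.
Degenerate inputs (constant sum image, <2 mask pixels, zero variance of
either channel within the mask) raise errors rather than reporting 0,
because 0 would read as "no mixing". Group comparison is the classical
pooled-variance unpaired two-tailed t test on per-cell PCC values. Note
that fully unmixed two-population images score strongly *negative* PCC
within the union mask (bright in one channel implies background in the
other), so the useful property is monotonicity in the mixed fraction, not
a [0, 1] range. Manders coefficients and Costes randomisation are out of
scope.

## Import traces and ΔΨ (`traces`)

**Amplitude.** A trace is a 30 s pre-injection luminescence baseline
followed by a rise to saturation. `baseline` is the mean of samples
strictly before 30 s; `plateau` is the mean of the final 10 % of samples
(configurable) — traces are acquired to saturation, so a tail mean
estimates the plateau without committing to a kinetic model;
`amplitude = plateau − baseline`, invariant to trace-wide offsets.

**Normalisation order (pinned).** (1) divide each well by its eqFP670
fluorescence (controls for acceptor abundance); (2) average technical
replicates per condition/time; (3) divide by the maximum amplitude of the
run; (4) divide by the control condition's amplitude → percent of
control. Swapping stages 3 and 4 changes percent-of-control whenever the
control is not the run maximum, and the test suite pins the order with a
constructed counterexample. "Maximum amplitude of the run" is implemented
as the maximum over the averaged condition traces in the run — the
protocol does not say whether it means conditions or wells; this choice
is flagged, not asserted as the original authors'. A missing control
yields stages 1–3 with percent-of-control NaN.

**Percent reduction** is `100·(1 − amp/amp_reference)` against the
no-trap/vehicle amplitude.

**TMRM.** `A` = mean of the first 10 frames (polarised steady state);
mitochondria are thresholded on `A`; `B` = mean of the final 3 frames
after CCCP has collapsed ΔΨ (background control); the statistic is the
mean of `A − B` within the mask. Series shorter than
`n_first + n_last` frames are rejected.

## Enrichment statistics (`enrichment`)

Intensities are median-centred per channel on the log2 scale, aligning
column medians to the *median* of the column medians: the robust target
makes the centring exact when a minority of channels carries a loading
artefact, and leaves already-centred tables untouched. Per protein, the
classical pooled-variance unpaired two-tailed t test on log2 intensities
compares the trap (+MTX) and imported (−MTX) groups (N = 3 biological
replicates by default); p-values are Benjamini–Hochberg adjusted across
proteins, which guarantees q ≥ p. Proteins with zero variance in both
groups get the documented fallback: p = 1 when the group means tie,
otherwise the smallest positive float. Volcano classes use an inclusive
≥2-fold cutoff: `enhanced_trap` if log2fc ≥ 1 with q < 0.05,
`enhanced_imported` if log2fc ≤ −1 with q < 0.05, else NS; classification
on raw p is available because the source figure is ambiguous about which
it used. `annotation_fraction` reports exact arithmetic for reference-set
overlaps (55 of 238 is 23.1 %).

## Synthetic ground truth (`synthetic`)

All generators route randomness through one `numpy.random.Generator`
seeded per call; a seed fully determines every output, bit for bit.

* **Tubular phantoms** — random smooth centrelines (heading noise sd =
  `curvature` rad/step, reflecting at the frame margins), rasterised with
  a 1-px anti-aliasing band, optionally branched, then PSF-blurred
  (Gaussian, default σ 1 px) and noised (Gaussian read noise, optional
  Poisson). The noiseless label map assigns pixels to tubes in draw
  order; pairs of tubes that overlap *or touch* are recorded so
  object-count oracles can reconcile connected components with the tube
  count by union-find. Fragmentation is controlled by `n_tubes` ×
  `tube_length_range`.
* **Enveloping shells** — a uniformly random subset of
  `round_half_away(fraction · n_objects)` organelles receives intensity
  in its exterior distance band `(0, shell_width]`; rounding is
  half-away-from-zero because recovery tests compare integer counts
  (0.433 × 200 → 87). Default shell 100 over noise sd 10 is the weakest
  (SNR 10) regime the recovery tests target.
* **Mixing images** — a `round_half_away(mix_fraction · n)` subset is
  labelled in both channels; the rest alternate between single-channel
  populations.
* **Import traces** — baseline noise for 30 s, then
  `A·(1 − exp(−rate·(t − 30 − lag)))` plus noise, in technical
  triplicate, scaled by a per-well eqFP670 value so stage-1 normalisation
  has real work to do. The lagged single exponential is a stand-in: only
  amplitudes are analysed downstream, so any monotone saturating form
  suffices; default rate 0.01 s⁻¹ saturates a 30-min read, dt = 6 s
  matches the coarsest acquisition the protocol allows.
* **TMRM movies** — objects at `mito_intensity` before the CCCP frame,
  `post_cccp_intensity` after, plus read noise.
* **Protein tables** — log-normal abundances (log2 base N(20, 2)),
  replicate scatter `replicate_sd` log2 units, and the first `n_enriched`
  proteins shifted by `log2_effect` in the +MTX group.

**What the generators do not emulate** — and hence what a green recovery
test does not establish: 3-D organelle geometry and cristae, SIM
reconstruction artefacts, spatially correlated noise or uneven
illumination, cytosolic precursor background in the association channel,
organelle motion between TMRM frames, kinetic shape of import traces
beyond a saturating rise, peptide-level effects (shared peptides, missing
values) in the protein tables, and any clustering of organelles beyond
uniform random placement. Estimator behaviour under those conditions must
be validated on real data.

## Determinism and orchestration

Every pipeline stage derives a sub-seed from the run seed, so a config +
seed reproduces all artifacts bit for bit; the run log records every
default actually used. Inferential statistics beyond the t tests above
(nested ANOVA, Tukey/Šidák) are deliberately left to standard statistical
software — they are routine and not this package's contribution. The
replicate summary (mean ± SD with per-replicate points) and the
proportion arithmetic for manually counted features are provided for
report assembly.

## Known limitations

* Skeleton-based branch statistics inherit the usual thinning artefacts;
  the 3-px spur pruning suppresses most, at the cost of erasing genuine
  sub-3-px branches.
* Width for organelles barely wider than 1 px sits at the digitisation
  floor and is flagged rather than extrapolated.
* The association score assumes the two channels are co-registered; no
  registration is performed.
* The contested-pixel exclusion margin trades a small loss of strip area
  for the removal of a crowding bias; in extremely dense fields many
  organelles may be flagged for empty annuli and per-cell fractions
  will rest on fewer objects.
* PCC within a union mask is a relative mixing score, not an absolute
  overlap measure.
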