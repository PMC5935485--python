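# Methods

This note documents the models, parameter choices and numerical
conventions behind `locshift`, and what the synthetic-data experiments do
and do not demonstrate.

## Localization profiles

Cells arrive with a fine cell-stage keypoint 1..10 (from upstream
segmentation, which estimates stage from bud size) and a mother/bud label.
Adjacent keypoints are merged pairwise (`ceil(keypoint/2)`) into 5 coarse
stages to keep per-bin cell counts workable, giving 10 bins (5 stages ×
mother/bud).  The pipeline is feature-agnostic: the five localization
features are treated as opaque columns with consistent units (the upstream
extractor provides biophysically motivated measures such as distance of
signal to the cell center).

The per-bin summary is a truncated mean: sort, drop `floor(trim·n)` values
from each tail, average the rest.

* `trim` default **0.05** per tail: mild robustness to stray segmentation
  artifacts without discarding data in small bins.  At n ≤ 19 the floor
  rounds to zero and nothing is trimmed — deliberate, so one- and two-cell
  bins are usable.  If trimming would drop everything, the median is
  returned.
* Vector layout (nowhere standardised upstream): bins are the major axis —
  mother stages 1–5 then bud stages 1–5 — with the five features varying
  fastest within each bin.  Column headers (`f2_b3` = feature 2, bud stage
  3) encode this in every file.
* The cell-count filter defaults to **≥1 cell in every bin** (the lenient
  variant; a stricter ≥5 is one argument away).

Abundance summaries are plain means of per-cell GFP intensity; screen
consistency is checked as squared Pearson correlation of per-protein means
over shared proteins.

## Change detection

For protein *p*, difference d = x_ref − x_target (so z > 0 ⇔ reference
value higher).  Each entry is standardised against the empirical mean and
sample SD (n−1) of the same entry over the k nearest neighbors of *p*.

* **Neighborhood space**: Euclidean distance between reference-screen
  profiles over mutually non-missing entries.  The expectation must be
  *local* in baseline-localization space, because global effects can
  depend on where a protein localizes; proteins with similar baselines
  experience similar distortions, so the distortion cancels in the
  standardised difference.
* `k` default **50** — small enough to stay local, large enough for a
  stable SD estimate.
* The query is excluded from its own neighborhood (self-inclusion shrinks
  its z toward zero).
* Ties in neighbor distance break lexicographically by protein id, making
  results order-independent.
* Per entry, at least `min_neighbors` = **10** neighbors must have a
  defined difference, else the entry is missing.  SD is floored at 1e−8;
  z is never clipped (genuine relocalizations reach |z| ≈ 30).
* Missing data propagate: missing in either profile ⇒ missing in d ⇒
  missing in z.  Nothing is imputed.  A protein absent from either screen
  yields an all-missing profile, not an exception.
* A protein that collapses from an expressed localization to background is
  *reported* as a large change, not suppressed — expression loss is a
  localization change for this analysis.

Change magnitude is the Euclidean norm of the non-missing z entries
(configurable block restriction); replicate agreement is the Pearson
correlation of per-protein magnitudes.

### Known limitation: co-moving neighbors

If a substantial fraction of a neighborhood relocalizes *in the same
direction* in the same screen, those neighbors inflate the local SD and
partially absorb the signal: with m such neighbors among k, z saturates
near √((k−m)/m) regardless of effect size.  At realistic densities (a
response group is a fraction of a percent of the proteome) this is
negligible, but desk-scale simulations that plant dense co-moving groups
must spread the change over protein-specific bin subsets (see below) or
accept reduced per-entry z.  This is a property of any local
standardisation, not an implementation artifact.

## Integration, filtering, clustering

Concatenation places each screen's 50 z entries in a fixed screen order;
screens missing a protein contribute all-missing blocks.  The
strong-signal filter keeps profiles with at least **3** entries |z| > **5.0**
(strict) and strictly more than **80%** of entries present.

Clustering uses the uncentered correlation distance
1 − Σxy/(‖x‖‖y‖) ∈ [0,2], computed pairwise-complete over mutually
observed entries (pairs sharing <2 entries are an error surfaced to the
caller), and unweighted average linkage: inter-cluster distance is the
arithmetic mean of all cross-pair *original* distances.  The linkage is
delegated to `scipy.cluster.hierarchy.linkage(method="average")`; tests
verify it against an independent O(n³) brute-force agglomerator to 1e−12.

Cluster extraction cuts the tree at a height the analyst chooses (the
original analysis curated clusters from the heat map by eye; a cut height
plus minimum size is the programmatic counterpart).  Rows only are
clustered; column clustering is out of scope.  CDT/GTR export writes the
matrix in leaf order with GID/UNIQID/NAME/GWEIGHT columns, empty fields
for missing values, and GTR node records whose scores are `1 − height`
(the correlation scale); the files re-read to the identical matrix,
missing mask, topology and leaf order.

## Comparative analyses

* Joint signal filter: a protein qualifies with ≥2 omics values |v| > 2.0
  (transcript log-fold; 50 for abundance deltas in intensity units) or ≥8
  localization entries |z| > 5.0; the union is kept.
* Pairwise profile distances for localization-vs-omics scatter use the
  *centered* Pearson correlation distance (1 − r), unlike the clustering
  metric, matching the convention for expression profile comparisons; both
  metrics are exposed.
* Interaction enrichment: observed = edges with both endpoints in a
  cluster; null = recount after uniformly shuffling proteins among cluster
  slots, preserving sizes.  The permutation universe is the union of
  clustered proteins (configurable), n_perm default **10,000**, z from the
  null sample mean/SD, z = 0 by convention when the null SD is 0.  An
  exhaustive enumerator (`ppi_enrichment_exhaustive`) provides exact
  moments for tiny universes and anchors the Monte Carlo path in tests.
* Annotation enrichment: one-sided hypergeometric upper tail per term,
  Benjamini–Hochberg across tested terms, significant at q ≤ 0.05.
* The magnitude-vs-abundance table joins per-protein change magnitude with
  |Δ mean GFP|; proteins present in only one input are dropped and logged.

## Pulse dynamics

Per frame, pixel intensities are modelled as
`w·Uniform(a,b) + (1−w)·Normal(μ_c, σ_c)` — diffuse cytoplasmic signal
plus a brighter nuclear pool spanning a wide intensity range.

* The uniform support (a,b) is pinned to the frame's observed min/max;
  estimating support inside EM is unstable at the 10²–10³ pixels per cell
  available.  Because (a,b) are data-determined they are counted as
  parameters in the BIC (5 vs 2 for the pure Gaussian).
* Nucleus visibility: mixture preferred by BIC *and* w ≥ `w_min` = 0.02;
  otherwise the frame is refit as pure Gaussian with w = 0.
* The localization score is the posterior-weighted share of total
  intensity, Σ P(nuclear|I)·I / Σ I ∈ [0,1] — a *relative* quantity,
  comparable across cells of different brightness (an absolute variant
  would just drop the denominator); 0 when no nucleus is visible.
* Pulse durations: `scipy.signal.find_peaks` with prominence ≥ 0.1
  (default), duration = peak width at **half prominence** with linearly
  interpolated crossings, × frame interval (default 2.5 min).  Missing
  frames are linearly interpolated for detection only and flagged in the
  trace.
* Group comparison: two-sample t-test, pooled variance by default (Welch
  optional), one-sided p from the t distribution with n_a+n_b−2 df.

## Synthetic data: what it emulates, and what not

`generate_screens` draws, per protein: a compartment archetype (4
well-separated 5-feature centroids by default), a per-protein baseline
jitter (SD 0.3), a deterministic cell-cycle modulation per bin, a
log-normal cell count (median **150** per protein per screen, σ=0.4 —
mimicking uneven proliferation; every bin is guaranteed ≥1 cell unless the
under-sampling switch is used), unit-SD Gaussian single-cell feature
noise, and log-normal GFP abundance shared across screens.  Screen-level
global effects are affine maps (scale+offset per feature), optionally
different per archetype — the localization-dependent bias that makes a
local expectation necessary.  Planted relocalizations displace affected
bin means by λ·σ_cell toward a target archetype, or along an explicit
shared direction, optionally restricted to bin/feature subsets
(stage-gated changes); replicate screens are validated to share plants.
Missingness removes whole (protein, screen) pairs at a configured rate.

The movie generator alternates off/on intervals (exponential by default;
fixed-duration for exact recovery checks) and draws, during "on" frames, a
fixed fraction (default 0.2) of pixels from Uniform(220, 1000) against a
Normal(200, 10) cytoplasm — nuclear pixels strictly brighter, nuclear
range wide, spanning most of the observed range so the support convention
is representable.

Not emulated: pixel-level images, segmentation errors beyond missingness,
bimodal expression, cell-cycle-dependent abundance, spatial correlation of
pixels.  Passing tests therefore demonstrate the *statistical* behaviour
of the pipeline under its own model assumptions — calibration, recovery,
invariances — not performance on real micrograph artifacts.

## Evaluation scenarios (benchmarks module)

Problem sizes are desk-scale choices: 1000 proteins × 2 screens for null
calibration and planted-recovery AUROC (50 planted, λ=2, 3 features); 500
proteins × 5 screens for the two-pattern clustering scenario (30+30
planted, λ=8, each protein's change gated to a random 3-of-10 bin subset,
shared per-group direction — see the co-moving-neighbor note above; the
tree is cut at 0.9, between the within-pattern distances of ~0.75–0.85
produced by partially overlapping bin subsets and the ~1.0 between
patterns); 20 clusters of 20 in a 400-protein universe for permutation
calibration (100 null graphs) and sensitivity (5× planted excess); 200
frames of 400 pixels for mixture recovery; fixed 50-min pulses in an 8-h
movie for duration recovery; 100 repeats of a 40-vs-40 power simulation at
group means 123 vs 175 min (SD 60), values taken from published pulsing
dynamics as simulation inputs.  Determinism: every scenario seeds
`numpy.random.default_rng` explicitly; no global RNG state.
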