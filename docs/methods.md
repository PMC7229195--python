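# Methods

## Scope and data model

`cnvrkit` operates downstream of the CNV callers: it consumes PennCNV
`rawcnv` text (array calls, `GEN`) and CNVnator tab text (read-depth
calls, `WGS`) and never re-implements the callers themselves. All
coordinates are held 1-based inclusive — both caller dialects print
1-based inclusive spans, so this minimizes off-by-one churn; only the
BED writer converts to 0-based half-open. Chromosome labels are
normalized by stripping a leading `chr` (the two dialects disagree),
and only autosomes (`1`–`29`) with known positions are analyzed.
Interval length is `end − start + 1`.

Of CNVnator's four e-values, the first is interpreted as the t-test
significance of the region's mean read depth against the sample average
and drives the p-value filter; the others are parsed but unused. The
sample id of an array call is derived from the signal-file token of the
`rawcnv` line (basename, extension stripped), with an optional override
map, because the dialect has no dedicated sample column.

## Quality filters

Samples (array QC): removed when LRR SD > 0.3, BAF drift > 0.01, or
|wave factor| > 0.05. The wave factor is signed in the array-QC
convention; the cutoff is treated as a magnitude — a design choice of
this package, since a one-sided cutoff would pass arbitrarily strong
negative waves. Removing a sample removes it from **both** data
sources, so the consensus denominators always refer to QC-passing
samples.

Array calls: a call must span ≥ 10 markers for HD-genotyped samples and
≥ 3 markers for any other panel. Read-depth calls: kept when
1 kb ≤ length ≤ 5 Mb, RD p-value < 0.05 and q0 (fraction of
mapping-quality-zero reads) < 0.5. Boundary semantics are literal
("above 0.3" removes only > 0.3; "shorter than 1 kb" removes only
< 1000 bp; a call of exactly 5 Mb is kept). Per-sample GenCall-score
marker filtering (score < 0.15 removed) is provided for the masking
utility; markers without a recorded score are kept.

Every filter returns a report with removals bucketed by the *first*
violated rule in a fixed order, so the record count is conserved
exactly (`n_input = n_passed + Σ removals`). Filters are idempotent and
independent rules commute in counts.

## Consensus pipelines

**Collation.** Regions are the transitive closure of "overlap ≥ 1 bp or
gap ≤ `contiguity_gap`" over same-chromosome calls, computed by a
single sorted sweep per chromosome. The default `contiguity_gap` of 0
merges directly adjacent calls (`end + 1 = start`) but not calls one
base apart; "contiguous" is not otherwise defined by the procedure this
implements, so the gap is exposed as a parameter. A region's interval
is the union span of its members; its type is CNL (all losses), CNG
(all gains) or MIX (both observed among carriers).

**Animal pipeline.** Within each sample, every (GEN, WGS) pair with
reciprocal overlap ≥ `reciprocal_min` (default 0.5, applied to both
fractions) yields one high-confidence CNV. Design choices where the
procedure is genuinely open:

* the high-confidence interval is the **union span** of the pair —
  consistent with the union semantics of the downstream collation
  (intersection or either member would be defensible alternatives);
* matching is **many-to-many**: all qualifying pairs are emitted and
  collation deduplicates, which makes the result deterministic and
  independent of call order (no greedy best-match);
* a pair whose events disagree (one loss, one gain) is **not** high
  confidence and is dropped with a logged count; cross-source event
  disagreement at the same locus in the same sample is more plausibly a
  caller artifact than a real variant.

**Population pipeline.** GEN and WGS calls are collated separately into
`GEN_CNVR` and `WGS_CNVR`; cross-source region pairs passing the
reciprocal threshold become candidates whose carrier set is the union
of the two regions' carriers. A candidate is kept when its carrier
frequency strictly exceeds `population_min_freq` (default 0.05;
"more than 5%" is a strict floor, while the non-strict "at least 5%"
variant used when loading published catalogues is also exposed). The
frequency denominator is the number of QC-passing samples in the run —
the genotyped-but-failed samples contribute no calls, so counting them
would deflate frequencies with no information gain. Retained candidates
are collated into the final set.

**Unique regions.** The union of both high-confidence sets is merged by
strict ≥ 1 bp overlap (no adjacency), so overlapping regions are
counted once; each merged region records which sets contributed.

**Threshold sweep.** The animal pipeline is re-run across reciprocal
thresholds (default 0.1–0.9); counts are non-increasing in the
threshold, which the tests verify on seeded synthetic data and on a
constructed set where every pair overlaps at exactly 0.6 (a step
function dropping to zero above 0.6).

## Marker-density false-positive experiment

Lower-density call sets are compared against HD calls from the same
samples. Calls across the three densities sharing ≥ 1 bp are one event;
clustering is transitive, and the Venn zones a–g are defined **on
clusters, not raw calls**, so the rate formulas stay well defined when
one event is fragmented into several calls at one density. With any
HD-supported event treated as true,
`fp_150 = (c + f)/n` and `fp_50 = (f + g)/n` per sample, where `n` is
the number of clusters. Uncertainty: percentile bootstrap of the
across-sample mean, resampling whole samples (the exchangeable unit,
since rates are per-sample statistics), 10,000 replicates, seed
required (default 20200515). The masking utility subsets an HD signal
table to the marker-name intersection with a lower-density manifest,
keeping HD positions.

## Synthetic data

The generator emulates the study conditions: 30 samples, 200 true
CNVRs, truth lengths log-uniform on 1.2 kb–1.3 Mb (the observed span of
call lengths across both sources), frequencies uniform on (0.02, 1.0),
70% losses (losses dominate both call sets in practice), panel mean
gaps 3.98 / 21.83 / 39.66 / 66.75 kb for HD / 150K / GGPHD / 50K,
sequence breakpoint jitter Normal(0, 0.05 × length), one false call per
sample per source (Poisson), 10% per-source dropout of carried events,
and 10% of samples violating one array-QC rule (the generator's own
default; the fraction observed in real cohorts varies widely and is
configurable). The default genome is 5 × 40 Mb chromosomes — compact
enough for fast tests while leaving truth occupancy under 20%.

Mechanics worth noting:

* lower-density panels are **nested subsets** of the HD panel, as in
  the masking design; inter-marker gaps are exponential (only the mean
  is matched), and thinning a renewal process by `p` scales its mean
  gap by `1/p`, which fixes the per-density keep probabilities;
* array breakpoints are snapped to the outermost panel markers inside
  the truth interval, and events spanning fewer than the panel minimum
  are silently undetectable — exactly the mechanism that creates
  density-dependent false positives;
* false calls pass every filter by construction (they stress the
  consensus, not the filters); `filter_stress=True` inverts this so
  each false call violates one rule;
* in the density experiment, injected density-only false calls are
  drawn per sample as Poisson with mean `r_d/(1 − Σr) × n_truth`, which
  makes the expected false fraction of the final union equal the
  requested rate `r_d`; injected intervals avoid truth regions and each
  other so they cannot join true clusters.

**What the generator does not emulate:** raw intensities or reads,
LRR/BAF signal values, caller-internal statistics, linkage between
nearby variants, reference-assembly gaps, segmental-duplication
hotspots, or platform-specific batch effects. Passing tests therefore
demonstrate the correctness of the consensus/filtering/statistics
machinery under a clean noise model, not caller performance on real
cattle data.

## Recovery metrics and the sensitivity denominator

A truth region is *recovered* when some reported region matches it at
reciprocal overlap ≥ 0.5. Sensitivity is reported over truth regions of
frequency ≥ 0.1, in two denominators: all such regions, and the
**array-assayable** subset spanning ≥ 10 HD markers. Under the default
length distribution roughly half of the truth regions lie below array
resolution and can never enter a cross-source consensus, so the
unconditional number (~45–55%) measures the length distribution, not
the pipeline; the assayable-denominator number (the standard
platform-resolution conditioning in CNV benchmarking) is the package's
headline sensitivity (≥ 90% expected at defaults; ~98% typical).
Precision is the fraction of reported regions matching any truth
region; false regions require two independent random calls from
different sources to reciprocally overlap in enough samples, so
precision is ~100% at default noise.

## Numerical and degenerate-input choices

* Reciprocal overlap of cross-chromosome or disjoint intervals is
  (0, 0); a pair passes a threshold via `min(frac_a, frac_b) ≥ t`.
* Collation of an empty call list returns an empty region list;
  `population_pipeline` with zero samples raises.
* An exact-threshold pair (e.g. 500 bp shared between two 1000 bp
  intervals at t = 0.5) **passes** ("at least 50%").
* Bootstrap of a constant list returns a degenerate interval; the empty
  list raises.
* Carrier counts in the generator are `max(1, round(freq × n))`, within
  one sample of the nominal frequency.
* Region/marker tables are sorted with numeric-aware chromosome keys;
  ties break on start then end, making every output order-free.
* All generator stages derive independent deterministic streams from
  the single seed (`default_rng([seed, stage])`), so stages can be
  re-run in isolation without disturbing each other's draws.

## Problem sizes

Default test and acceptance scales — 30 samples, 200 truth regions,
200 Mb genome, 20 replicate datasets for the sweep-monotonicity and
FP-recovery checks, 10,000 bootstrap replicates — were chosen so the
statistics of interest (coverage of injected rates, monotonicity,
recovery fractions) are stable across seeds while a full run stays in
the tens of seconds on one core.

## Known limitations

* The consensus inherits both callers' blind spots; a variant missed by
  either source can never be high confidence.
* The density experiment treats any HD-supported event as true, so its
  false-positive rates are lower bounds.
* Catalogue comparison assumes coordinates already on the working
  assembly; no liftOver is performed.
* MIX typing depends on observed carriers only; sparse sampling can
  type a truly mixed region as CNL or CNG.
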