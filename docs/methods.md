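# Methods

## Data model and transform

Events are dense per-sample matrices over an ordered marker panel
(reference panel: CD45, CD31, PDPN, ICAM-1, VCAM-1). All distributional
machinery operates on compensated linear intensities; clustering,
embedding and similarity work on arcsinh(x / cofactor) with a default
cofactor of 150 per channel — the conventional variance-stabilizing
choice for fluorescence (non-mass) cytometry, monotone and defined for
the negative values compensation can produce. Normalization is applied
on the linear scale *before* the transform, because the two-point model
is derived in measured-intensity units.

FCS support targets FCS 3.0/3.1 list mode with float, double or
unsigned-integer data and the two common byte orders; `$PnE`
log-amplification and `$PnG` gain are applied so values are returned on
the linear scale. Other dialects are rejected with a clear error rather
than guessed. The FCS writer is a fixture writer (float32, little
endian) for round-trip testing, not a production exporter.

## Two-point bead normalization

Per channel and day, the bead peaks are found by a Gaussian KDE
(Silverman bandwidth) on the arcsinh scale; the two highest modes are
kept, events are split at the deepest density valley between them, and
the median (default; mean available) of each side taken on the linear
scale. Fewer than two modes raises a unimodal error; modes closer than
0.5 arcsinh units raise an ambiguous-peaks error (both thresholds
configurable).

The normalization maps the source day's (low, high) anchors exactly
onto the reference day's. The reference day defaults to the day with
the higher mean positive-peak signal, so lower-signal days are
amplified onto it (the direction also used in practice); this is
configurable. Channels whose anchors already agree within 1% relative
keep the identity map so that no noise is amplified where there is no
batch effect. The per-channel slope ratio is always reported: a ratio
above 1 widens the normalized day's distributions, which mostly affects
low-signal populations — this caveat is intrinsic to the method, not an
implementation artifact. All samples of a source day (beads, unlabeled,
labeled) are normalized uniformly.

## Sequential gating and the variation study

Layer 1 gates CD45 with a cutoff retaining a configured fraction
(retention; 0.995 / 0.999 / 1.0 are the study variants) of *every*
unlabeled-control sample — with two controls the larger per-sample
cutoff wins. Layer 2 forms CD31/PDPN quadrants of the CD45-negative
events (double-negative → PvC_DN, CD31+PDPN− → BEC, CD31+PDPN+ → LEC,
CD31−PDPN+ → FRC); the BEC quadrant is labeled even when nearly empty
so that the partition stays total. Layer 3 forms ICAM-1/VCAM-1
quadrants within FRC and PvC_DN. Oblique (diagonal-line) negative gates
are supported via a signed-area side test; axis-aligned is the default.

The variation study reruns the cascade per criterion and reports, per
population, the coefficient of variation of counts: sample
(n−1)-denominator SD divided by the mean, as a percent. "Covariance" in
the colloquial sense used for this comparison is read as CV throughout;
a covariance matrix plays no role. Subjective gate draggings are
modeled as retention variants plus an optional multiplicative cutoff
margin — an approximation of hand placement, not a reproduction of it.
Per-layer mean CVs expose the compounding of placement variation with
depth.

## Clusterers

All three run on full-dimensional transformed data; embeddings are
never an input to labels.

* **SOM metaclustering** — a batch-trained self-organizing map
  (default 10×10 grid, 10 epochs, exponentially shrinking neighborhood)
  whose codebook is Ward-agglomerated into `k_meta` metaclusters
  (default 7); events inherit their best-matching node's metacluster.
* **Graph communities** — exact kNN graph (Euclidean, default k=30),
  shared-neighbour Jaccard edge weights, Leiden modularity
  maximization with a fixed seed.
* **Density peaks** — density as inverse mean distance to the k nearest
  neighbours (default k=30); each event links to its nearest
  higher-density neighbour within its neighbour list; link-free events
  are peaks and clusters are the trees rooted at them. Deterministic;
  density ties break toward the lower event index. This is a
  deliberately simple density-gradient assigner: no cross-validated k
  selection or model-selection elbow — the consensus layer, not any
  single clusterer, carries the result.

The "low/default/high" parameter levels used by the robustness sweep
are (8×8, k_meta 5, k 15), (10×10, 7, 30) and (12×12, 9, 45).

## Consensus

A seeded uniform subsample (default cap 5000 events) defines a
co-association matrix: the fraction of clusterings placing each pair
together. Average linkage on (1 − co-association) is cut at 0.5 —
pairs co-clustered by a majority of algorithms stay together — and
events outside the subsample join the nearest group centroid in marker
space. Clusters with ≥ 90% of events from one control sample type are
anchored: a dominant single-stain bead sample gives a `bead_control`
role, bead-dominated clusters without a dominant stain are the pooled
negative beads, unlabeled-dominated clusters are the unlabeled anchor;
same-role clusters merge unconditionally.

Remaining labeled clusters merge pairwise, smallest pair first,
repeated to a fixed point, when **either**

* their robust standardized location difference is small — per
  channel, |Δmedian| / pooled scaled MAD (1.4826·MAD, RMS-pooled,
  floored at 1e−6 for zero-spread channels), aggregated as the max over
  channels, below 3 — **or**
* their control-adjusted T(x) is ≤ 0 on every channel.

The overlap arm exists because density-driven algorithms split large
populations along *spatially coherent* boundaries; such halves always
differ in distribution (a T(x) test keeps them apart forever) yet are
exactly the splits a practitioner merges as "extensive overlap, no
place to draw a gate". The distribution arm merges genuinely
indistinguishable clusters regardless of geometry; merges that happen
on this arm despite a large location difference are flagged
`borderline` in the audit log. The threshold of 3 robust-SD was
calibrated on the synthetic recovery suite: measured within-population
split aggregates are ≈1.5–2.0 and cross-population aggregates ≈9–15,
so 3 sits well inside the gap. Every anchor assignment, merge, and
rejected pair is written to the audit log.

Cross-embedding consistency is a diagnostic score per population: the
fraction of 2-D layouts in which the population's best Jaccard overlap
with a density island (gridded KDE, connected foreground components)
reaches 0.5. The degenerate density quantile 0 means "no background":
one island holding all events.

## Probability-binning T(x)

Univariate schemes use equal-occupancy quantile bins; multivariate
schemes use a recursive split tree that always splits the region with
the larger leaf budget on its highest-variance channel, at the order
statistic proportional to the budget split (the median when the budget
halves evenly) — both constructions keep control occupancy even to
within one event. B never exceeds ⌊n/10⌋ of the smaller compared
sample.

The χ² is the two-sample occupancy statistic
`n_c·n_t/(n_c+n_t) · Σ (F_c − F_t)²/(F_c + F_t)`. Null moments come
from a seeded Monte-Carlo (default 200 replicates, cached per
(n_control, n_test, B)) that replays the full procedure on a continuous
reference distribution — quantile binning makes the null
distribution-free, and the same equal-occupancy null serves both
schemes. Results carry both `z` (the unfloored standardized χ², which
averages 0 under the null) and `tx = max(0, z)`; the floor means the
*reported* score has a null mean of E[max(0,Z)] ≈ 0.4 by construction,
which is truncation, not miscalibration. Under the null fewer than 5%
of pairs score tx > 3.

Control adjustment: the variability level per channel is the maximum
day-1-vs-day-2 T(x) over the unlabeled-cells control and each bead
control, excluding any control whose day-to-day T(x) exceeds the
unlabeled one (transform amplification inflates low-signal bead
controls; biology cannot exceed the biological control). Significant
means T(x) against the pooled unlabeled reference minus that level is
positive. No multiple-testing correction is applied — the significance
rule is a subtraction against measured control variability, and adding
one would change the method being implemented; this is a documented
limitation. Marker positivity additionally requires the population
median to exceed the unlabeled 99th percentile, so negative shifts
cannot be called "positive"; phenotype strings map the known patterns
(all five → hematopoietic; CD31+PDPN+ICAM1+VCAM1+ → LEC; VCAM1 only →
PvC; PDPN+VCAM1+ → FRC; PDPN+ICAM1+VCAM1+ → MRC-like; anything else →
unassigned).

Population tables report counts and percentages (of total labeled
cells and of each passage's cells) rounded half-up to two decimals,
with a totals row; percentages always re-derive exactly from the
table's own counts.

## Synthetic studies

The generator emulates the assumed design: per day, five single-stain
bead samples (50/50 sharp negative/positive peaks on the stained
channel, negative level elsewhere), one unlabeled sample
(autofluorescence only) and one labeled sample drawn multinomially from
the population proportions of that day's passage (passage 5 on day 1,
passage 12 on day 2). Signals are log-normal around a linear-scale
median on top of a log-normal autofluorescence floor — reproducing the
heavy tails and orders-of-magnitude span of fluorescence data. The
default batch effect is an affine ICAM-1 distortion on day 2 (gain 0.4,
offset +20), large enough that naive pooling misaligns the days; its
magnitude is illustrative, chosen once, not calibrated to any real
acquisition. The reference proportions are the profiled passage
breakdown (P5: 7.81 / 5.44 / 0.41 / 86.34%; P12: 0.01 / 0.27 / 5.84 /
93.88% for the hematopoietic / LEC / PvC / FRC-like populations). An
MRC-like subpopulation (FRC with raised ICAM-1) can be carved from the
FRC fraction via `mrc_fraction` to exercise
near-indistinguishable-population behaviour; it is off in the reference
design. The `overlapping` preset (quartered positive signals, doubled
spreads) is used for gating-robustness studies.

What the generator does **not** model: spillover and compensation
error, acquisition drift within a run, doublets and debris, day-to-day
biological drift of cell populations, and non-specific antibody
binding. Passing tests therefore demonstrate the pipeline's behaviour
under its own assumptions — clean affine batch effects and log-normal
populations — not performance on arbitrary real data.

## Problem sizes and determinism

Tests run the pipeline at 800 bead / 2500 cell events per sample
(≈21k pooled events) and the robustness comparison at 400/1200
(≈8.8k); the acceptance script uses the full reference design
(5k/20k, ≈130k pooled events), which completes in about a minute on one
CPU. These sizes were chosen so the per-population expected counts
(including the 0.41% PvC fraction at P5) stay comfortably above the
clustering resolution limit. Every stochastic step — generation,
subsampling, SOM initialization, Leiden, the Monte-Carlo null — is
seeded; reruns with the same configuration are byte-identical.

## Known limitations

* The consensus depends on at least one clusterer keeping each true
  population intact somewhere in the vote; three algorithms of genuinely
  different bias make this likely but not guaranteed.
* The similarity merge threshold (3 robust-SD) is a calibrated artifact
  choice; populations separated by less than ~3 robust-SD on every
  channel will be merged deliberately (that is the
  near-indistinguishable regime).
* T(x) values are tied to this package's Monte-Carlo standardization;
  they are comparable within an analysis, not across tools with other
  normalization constants.
* The FCS reader covers common 3.0/3.1 list-mode files only.
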