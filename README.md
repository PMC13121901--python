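# cytoconsensus

Consensus analysis of heterogeneous flow-cytometry populations.

Small marker panels and limited controls make heterogeneous cell lines —
the motivating system is a cultured lymph-node stromal cell (LNSC) line
profiled with CD45, CD31, PDPN, ICAM-1 and VCAM-1 across two acquisition
days — hard to analyze: populations overlap along every single axis,
gate placement becomes subjective, and that subjectivity compounds with
each gating layer. `cytoconsensus` implements a reproducible version of
the alternative: let several clustering algorithms with *different*
inductive biases vote, anchor the result on the study's own controls,
and validate populations with a probability-binning χ² statistic.

The pipeline:

1. **Bead-anchored batch normalization.** Single-stain compensation
   beads give one sharp negative and one sharp positive peak per
   channel on every day. Assuming the number of bound antibodies per
   bead is day-invariant, the two peaks anchor a unique affine map
   between the days' intensity scales:

   `I₁ = (I₁ᴴᶜ − I₁ᴸᶜ)/(I₂ᴴᶜ − I₂ᴸᶜ) · (I₂ − I₂ᴸᶜ) + I₁ᴸᶜ`

   where `Lᶜ/Hᶜ` are the median (or mean) of the lower/higher control
   peak. The slope ratio is reported per channel because a ratio above
   1 amplifies the normalized day's spread — the method's main caveat.
2. **Traditional sequential gating** (CD45 → CD31/PDPN quadrants →
   ICAM-1/VCAM-1 quadrants), with a variation study that re-places
   every negative gate under several retention criteria (the fraction
   of unlabeled-control events kept inside the gate) and reports the
   coefficient of variation (CV) of population counts — the robustness
   baseline.
3. **Three clusterers** on the full-dimensional arcsinh-transformed
   data: SOM metaclustering, kNN-graph Leiden modularity communities,
   and density-peak assignment. 2-D embeddings (t-SNE, UMAP) are
   diagnostics, not inputs.
4. **Co-association consensus**: the fraction of clusterings placing
   each event pair together, average-linkage grouped and cut at a
   majority level; control-dominated clusters are anchored to their
   roles; remaining labeled clusters merge to a fixed point when they
   heavily overlap or are statistically indistinguishable.
5. **Probability-binning χ² `T(x)`**: bins hold equal control counts
   (never more than 10% of the smaller sample); the χ² of test-vs-
   control occupancy is standardized against a seeded Monte-Carlo null
   and floored at 0. Significance is control-adjusted: the day-to-day
   `T(x)` of the study's own controls sets the variability level
   (controls more variable than the unlabeled cells are excluded), and
   a population is positive for a marker only when it clears that
   level *and* its median exceeds the unlabeled 99th percentile.

A synthetic-study generator reproduces the assumed sample design (five
single-stain bead samples, unlabeled cells and labeled cells per day,
two passages with shifting population proportions, a strong ICAM-1-like
gain distortion on day 2), so every stage is testable end to end
without any data download.

## Worked example

```python
from cytoconsensus import generate_study, normalize_study, reference_design
from cytoconsensus.pipeline import run_consensus

design = reference_design(events_per_sample={"bead": 800,
                                             "unlabeled": 2500,
                                             "labeled": 2500})
study = generate_study(design, seed=7)

normalized, report = normalize_study(study)
print(report[report.day == 2][["channel", "slope_ratio", "identity"]]
      .to_string(index=False))

pops, events, meta = run_consensus(study, seed=7, coassoc_subsample=2000,
                                   null_reps=100, b_requested=50)
print(f"{len(pops.roles)} populations")
for name in sorted(pops.roles):
    n = int((pops.labels == name).sum())
    print(f"{name:<18s} {pops.roles[name]:<20s} {n:>6d} events")
```

prints

```
channel  slope_ratio  identity
   CD45     0.977108     False
   CD31     1.000000      True
   PDPN     1.000000      True
  ICAM1     2.479191     False
  VCAM1     1.029784     False

11 populations
bead_CD31          bead_control:CD31       786 events
bead_CD45          bead_control:CD45       811 events
bead_ICAM1         bead_control:ICAM1      782 events
bead_PDPN          bead_control:PDPN       816 events
bead_VCAM1         bead_control:VCAM1      798 events
negative_beads     negative_beads         4012 events
population_1       labeled_population     4480 events
population_2       labeled_population      191 events
population_3       labeled_population      172 events
population_4       labeled_population      157 events
unlabeled_cells    unlabeled_cells        4995 events
```

The slope ratio of ≈2.48 on ICAM-1 is the fitted correction for the
simulated day-2 gain loss (0.4× plus offset); CD31 and PDPN show no
batch effect and keep the identity model. The consensus finds the full
structure: five positive-bead anchors, the pooled negative beads, the
unlabeled cells, and four labeled-cell populations whose sizes match
the generating proportions (the large one is the FRC-like bulk, the
small ones the hematopoietic, PvC-like and LEC-like fractions).

There is also a CLI over the same machinery:

```bash
cytoconsensus simulate  --seed 7 --out study_dir     # write a study as CSVs
cytoconsensus normalize --seed 7 --out out           # per-channel model report
cytoconsensus all       --seed 7 --out out           # full report bundle
```

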