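# Methods notes

## The analysis model

The pipeline treats a stage × replicate microarray experiment as three
nested decisions per probe: *is it expressed at all* (detection call against
a hard platform limit), *where is it expressed* (stage/period specificity
from replicate-consensus calls), and *how does its abundance move*
(reference-anchored fold change plus one-way ANOVA among genes expressed
everywhere).  The assumptions are those of the classical
present/absent protocol: the detection limit is a property of the platform,
not estimated from the data; replicate discordance (one replicate present,
one absent) is treated as uninterpretable (INS) rather than averaged; and
differential expression among shared genes is assessed on the normalized
log2 scale with a fixed-effects one-way ANOVA — no moderated variance
shrinkage, mirroring the protocol this package reimplements.  Fold changes
are differences of replicate-mean log2 intensities (never means of ratios),
so the DE gate |log2FC| ≥ log2(2) is symmetric in direction and invariant to
adding a constant to the whole matrix.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `detection_limit` | 6.0 | log2 intensity | platform property; always explicit, never inferred |
| `baseline_mean`, `baseline_sd` | 11.0, 1.0 | log2 | present-probe intensity distribution, comfortably above the limit |
| `replicate_sd` | 0.15 | log2 | within-stage biological+technical noise; truncated at ±3σ (below) |
| `discordance_rate` | 0.0 | probability/cell | stochastic channel for replicate discordance; the default composition plants discordance explicitly instead |
| `de_fold_range` | (4, 12) | linear fold | planted DE amplitudes; lower bound chosen so the 2-fold gate is cleared deterministically under the noise bound |
| `fc_threshold`, `alpha` | 2.0, 0.05 | fold, p | DE gates (boundary inclusive for FC, strict for p) |
| `k_clusters` | 6 | — | the canonical temporal pattern count |
| `enrich_p` | 0.01 | p | raw hypergeometric flagging threshold |

## What the generator emulates — and the margins that make it exact

The default `class_counts` plant the full study composition (the printed
per-class counts sum exactly to the 39,724-probe array): 8,942 probes absent
everywhere, 8,275 replicate-discordant in one or two stages (two with
probability 0.58, tuned so discordant cells are ≈ 4.7 % of probe-stage
cells, i.e. ≈ 95 % replicate agreement), 712 stage-specific probes
(141/48/475 at 10/30/120 DAT, 12 at each remaining stage), 1,840
period-specific probes (58 at {10,15}, 16 at {15,20}, 123 further two-stage,
and 1,643 spread over contiguous three-to-six-stage windows chosen by the
seed), and 19,955 shared probes of which 5,368 follow the six DE templates.

Three margin rules make the downstream bookkeeping deterministic rather than
merely probable:

* replicate noise is a **3σ-truncated** Gaussian, and present cells are
  floored at the detection limit, so a planted-present cell can never be
  called absent;
* absent cells are drawn uniformly on
  [limit − `absent_spread`, limit − `replicate_sd`], strictly below the
  limit;
* per-probe baselines are clipped so that baseline + min(template offset) ≥
  limit + `present_margin` (1.0), so down-regulated templates never dip
  under the limit.

With `replicate_sd` = 0.15 the worst-case error of a stage-mean difference
is bounded by 2 × 3σ = 0.9 log2 units.  Planted DE amplitudes start at
log2 4 = 2, so every planted DE gene clears the |log2FC| ≥ 1 gate with ≥ 1.1
to spare, and no flat (constitutive) gene can reach it.  That is why a
default run reports the DE count and fraction (5,368; 26.9 %) exactly, and
why the acceptance checks can compare integers rather than distributions.
The cost is realism at the margins: planted fold changes are 4–12×, i.e.
the generator does not populate the 2–4× band that dominates real DE sets.

### Six temporal templates

Cluster templates are log2 offsets from the 10 DAT reference, scaled by a
per-gene amplitude: I, a spike at 30 DAT; II, a spike at 60 DAT; III, a
plateau from 15 through 90 DAT; IV, a dip at 20 DAT; V and VI, monotone
ramps.  The ramps move along a non-uniform *developmental drift* axis
(positions 0, 0.08, 0.16, 0.60, 0.66, 0.72, 1.0) rather than calendar time:
adjacent early stages are nearly identical, 30–90 DAT is almost flat, and
the 20→30 and 90→120 transitions are large.  This mirrors the observed
stage-correlation structure of root development (adjacent early stages
r ≈ 0.95, 30–90 DAT mutually ≈ 0.95, first versus last stage ≈ 0.7) and
guarantees, by construction, that the stage-mean correlation between
neighbouring stages exceeds that between the first and last stage.

### What synthetic data does not show

Passing tests on this generator demonstrate the *logic* of the pipeline —
partition completeness, conservation identities, gate boundaries, planted
recovery — not its behaviour on real arrays.  Real data have probe-specific
variances, intensity-dependent noise, spatial artifacts and annotation
error, none of which are modelled; absent-cell intensities are i.i.d.
uniform draws, so cross-stage correlations among absent probes are zero
rather than platform-structured; and TF annotations in the synthetic tables
are random labels.  Quantities that depend on the real data distribution —
cumulative expressed totals, per-stage detected counts, TF family tallies,
absolute correlation values, and any GO/KEGG term list — are therefore out
of reach of the synthetic runs and are not asserted anywhere.

One consequence worth spelling out: with the study composition planted, the
475 probes specific to 120 DAT make that stage by far the most distinct
sample (a presence/absence mismatch moves a probe ≈ 5–6 log2 units, dwarfing
any quantitative offset), so the two-group cut of the full-composition
sample dendrogram isolates 120 DAT.  The early-versus-late two-subtree
structure seen in real root data is reproduced — and tested — on
compositions dominated by the temporally smooth monotone templates, where
the drift axis puts the largest gap between 20 and 30 DAT.

## Numerical choices

* **Boundary convention**: intensity exactly equal to the detection limit is
  called present.
* **Degenerate ANOVA**: zero within-group and zero between-group variance →
  (F = 0, p = 1); zero within-group with non-zero between-group variance →
  (F = ∞, p = 0).  Variances are compared against a 1e−12-scaled tolerance.
* **Z-score conventions**: "global" (default) takes μ_G, σ_G over all
  gene × sample values (population SD, so the standardized matrix has mean 0
  and SD exactly 1); "sample_means" derives them from the per-sample mean
  intensities.  The convention used is recorded on the output.
* **Clustering determinism**: distances are 1 − Pearson on Z-profiles by
  default (Euclidean optional); merge ties follow scipy's deterministic
  lowest-index order; flat profiles (undefined correlation) are held out of
  the dendrogram and attached post hoc to the nearest centroid; cluster ids
  are renumbered by first appearance so labels are reproducible for a fixed
  input order.
* **Template labelling**: greedy one-to-one centroid↔template assignment by
  Pearson correlation, `unmatched` below r = 0.5.
* **PCA sign**: each component is flipped so its largest-magnitude loading
  is positive.
* **Zero-variance correlations** are reported as NaN (undefined), never 0.
* **Hypergeometric p** is the upper tail including the point mass,
  `sf(k−1)`, clamped to (0, 1].

## Problem sizes

The full 39,724-probe composition runs in seconds, so the bookkeeping tests
and the acceptance script use it directly.  End-to-end recovery, determinism
and pattern-recovery properties run on a 1/10-scaled copy of the composition
(≈ 4,000 probes) or on purpose-built small compositions — sizes chosen to
keep the whole suite fast while leaving every code path identical.

## Known limitations

* Single-replicate stages are supported only behind an explicit flag
  (consensus degenerates to the single call); concordance statistics then
  report agreement 1 by construction.
* The enrichment module tests flat term sets only — no GO DAG propagation,
  no pathway topology, no depletion tail.
* No raw-array (pair/XYS) input or RMA normalization: the pipeline starts
  from a normalized log2 matrix.
* Plotting is left to the caller; all outputs are tab-delimited tables and
  Newick trees that drop straight into pandas/seaborn or R.
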