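# Methods

## The measurement model

The pipeline treats a two-condition RNA-seq study (control vs. knockout,
several tissues, n replicates each) as three coupled measurements per
gene:

* **Mature mRNA abundance.** Reads fully contained in a gene's exon
  union are exonic; FPKM is reads per kilobase of exon union per million
  exonic-assigned reads in the sample. Expression values are FPKM
  divided by the sample's *Gapdh* FPKM. This internal-control
  normalization makes values invariant to global per-sample depth
  changes (and, during a shutoff chase, re-anchors the decaying pool to
  a stable reference — see below).
* **mRNA stability.** After chemical transcription shutoff
  (actinomycin D), mRNA decays approximately as
  `y(t) = y(0)·2^(−t/t½)`. With expression measured at 0, 4 and 8 h,
  replicate-averaged values are normalized to t = 0 and
  `ln(y(t)/y(0))` is regressed on `t` by ordinary least squares
  (`scipy.stats.linregress`). The reported half-life is the time at
  which the fitted line crosses relative abundance 0.5:
  `t½ = (ln 0.5 − β₀)/β₁`. Because values are pre-normalized the
  intercept β₀ is near zero, but the fit is *not* forced through the
  origin and the intercept enters the estimate exactly as written. The
  alternative "time for the fitted curve to halve from its own fitted
  t = 0 value" (`ln 0.5/β₁`) is reported as `time_to_half_h` for
  diagnostics only; with a nonzero intercept the two differ, and the
  intercept-bearing form is canonical.
* **Transcription.** Reads overlapping any intronic base of exactly one
  gene are intronic; intronic FPKM (iFPKM) applies the identical density
  formula with summed intron length and the sample's total intronic
  reads. Pre-mRNA is short-lived relative to mRNA, so intronic signal
  tracks the synthesis rate rather than the mature pool — the standard
  pre-mRNA proxy for transcription rate.

### Read assignment

A read interval entirely inside the exon union is exonic; a read
overlapping any intronic base of exactly one gene is intronic; reads
overlapping no gene or more than one gene are discarded and tallied per
sample with a reason (`no_gene`, `multi_gene`, `partial_overlap`).
Requiring full exonic containment maximizes the specificity of the
intronic (pre-mRNA) signal: any read touching an intron counts as
nascent. Reads are single intervals; paired mates would be counted
independently. Assignment is unstranded; strand is carried on gene
models but does not affect lengths or counting.

### Gene geometry

Internally all coordinates are 0-based half-open; GTF I/O converts at
the boundary. Exons of all transcripts of a gene are merged (overlapping
or book-ended intervals union) and introns are exactly the gaps between
merged exons. For multi-isoform genes this "union" convention defines
exonic as *ever exonic in any transcript*; genes whose spans overlap
another gene are flagged in the geometry output because the exon/intron
split is ambiguous there.

## Thresholds and filters

| parameter | default | meaning |
|---|---|---|
| `expr_min_fpkm` | 0.1 | genes below this condition-mean FPKM are excluded (boundary passes) |
| biotype | protein_coding | only protein-coding genes enter comparisons |
| `ifpkm_min` | 0.001 | intronic-layer floor on condition-mean iFPKM |
| `intron_min_bp` | 150 | minimum summed intron length for the intronic layer |
| `hl_min`, `hl_max` | 0, 50 h | retained half-life window (strict outside) |
| `up`, `down` | 2.0, 0.5 | fold-change class thresholds, strict inequalities (`up=2.5` mirrors the brown-fat style analysis) |
| `stabilized_ratio`, `destabilized_ratio` | 2.0, 0.5 | half-life-ratio call thresholds |
| `fdr`, `max_terms` | 0.05, 6 | enrichment shortlist rule |

All inequalities at class boundaries are strict (a ratio of exactly 2.0
is unchanged; a half-life of exactly 50 h is retained; an FPKM of
exactly 0.1 passes). Filters are evaluated on the per-condition
replicate-mean value, and by default a gene must clear the floor in
**all** conditions entering a comparison (`expr_filter_scope="all"`);
this avoids undefined ratios from zero control means and is switchable
to `"any"`. Genes removed by a layer's filter get **no call** in that
layer, never "unchanged".

Two quantities in the FPKM family are conventions rather than
measurements. The FPKM denominator is the total of exonic-assigned reads
in the sample (a per-sample mapped total can be supplied instead); a
"retained-genes-only" denominator would be circular, since retention
itself depends on FPKM. The iFPKM scale constant is 10⁹, mirroring FPKM;
any constant cancels in KO/control ratios, so classifications do not
depend on it.

## Decay fitting details

Time points with non-positive expression are dropped (their log is
undefined — zeros are not imputed); fewer than two usable points, a zero
value at t = 0, or a numerically flat series excludes the gene with a
recorded reason. Exclusion by the half-life window (below 0 h, i.e. a
rising fit, or above 50 h, unmeasurable over an 8 h chase) and by the
0.1 FPKM floor at t = 0 happens after fitting, so excluded fits remain
inspectable with their reasons. Replicates are averaged per time point
before fitting by default; per-replicate fitting (half-lives averaged
over retained replicate fits) is available behind a flag. The natural
log is used throughout; half-lives are unit-consistent (fitting in
minutes and converting gives identical hours).

Chase values are Gapdh-normalized like steady-state expression. This is
a substantive choice: per-sample FPKM totals renormalize away the global
decay of the whole transcriptome under shutoff, so the absolute decay
signal survives *only* in the ratio to a stable internal control. The
cost is a shared bias if Gapdh itself decays appreciably — the effective
rate is `1/t½(gene) − 1/t½(Gapdh)` — which cancels almost entirely in
KO/control half-life *ratios* and is negligible for a long-lived
control.

## Driver attribution

Attribution is defined for genes whose mRNA class is `up` or `down`
(the quantity being attributed is an expression change). Stabilized
counts as the "up" direction, destabilized as "down"; then per gene:

| stability | pre-mRNA | driver |
|---|---|---|
| concordant | concordant | both |
| concordant | unchanged / no call | stability |
| unchanged / no call | concordant | transcription |
| opposing (either layer) | | discordant |
| anything else | | unexplained |

A layer with no call neither supports nor opposes: a concordant
half-life change with missing intronic data still reads as
stability-driven, but two silent layers leave the change unexplained
rather than guessed. This per-gene rule table is this package's
formalization of an analysis style that compares the three layers'
gene-list profiles; the list-level comparison remains available through
the enrichment module.

## Overrepresentation test

The hypergeometric upper tail `P(X ≥ k)` for an overlap of `k` between a
query of `n` genes and a term with `K` members in a universe of `N`,
with the universe restricted to genes passing the relevant layer's
filter (the population the query was actually drawn from). P-values are
BH-adjusted across tested terms; the shortlist keeps at most six terms
with FDR strictly below 0.05, ranked by FDR with ties broken by larger
overlap then term id. This is deliberately a plain, fully reproducible
test — no curated background, no modified statistic — so term lists from
web services with proprietary backgrounds will not be reproduced
term-for-term. Note the discrete test is conservative: its null
p-values are super-uniform, which is what the calibration test asserts
(exact chi-square on overlap counts plus `P(p ≤ α) ≤ α`).

## ΔΔCt

Per sample, `ΔCt = Ct(target) − Ct(reference)`; `ΔΔCt` subtracts the
arithmetic mean ΔCt of the control group per target (equivalently, the
geometric mean of control fold changes is 1 by construction); relative
expression is `2^(−ΔΔCt)`, assuming perfect per-cycle doubling. Plate-
wide Ct shifts cancel exactly. Efficiency-corrected models are out of
scope.

## The synthetic-data generator

The generator is the package's ground-truth instrument, built on the
minimal kinetic model linking the three layers: steady-state abundance =
transcription rate × t½ / ln 2. Defaults define the standard study:

* 300 genes; 10% each designed stabilized, destabilized,
  transcription-up, transcription-down (one kinetic parameter perturbed
  by 4.0× or 0.25×); the rest null.
* two conditions × 4 replicates; chase at 0/4/8 h; 3×10⁶ reads per
  sample, 10% of depth in the intronic compartment.
* base half-lives log-uniform in [2, 10] h (so ×4 stays within the 50 h
  window and ×0.25 above the measurable floor); transcription rates
  log-normal (median 10, σ = 1 on the log scale).
* a planted *Gapdh* with identical parameters in both conditions and a
  1×10⁶ h half-life — effectively stable, so reference-normalized chase
  values carry the decay signal, and its own fit is properly discarded
  by the > 50 h rule.
* exonic count expectations ∝ abundance × exon-union length; intronic
  expectations ∝ transcription rate × intron length (pre-mRNA tracks
  synthesis, not the mature pool); chase expectations decay as
  `2^(−t/t½)` with transcription assumed fully and instantly shut off.
  Counts are Poisson; an optional gamma overdispersion parameter
  stress-tests the filters.

Designed genes always get ≥ 2 exons and ≥ 150 bp of intron, so every
planted effect is recoverable *through* the standard filters; null genes
include single-exon models, sub-150 bp introns and a few non-coding
biotypes, which is exactly the material those filters must remove.
Per-read BED output (reads placed uniformly within single exons or
introns) is generated on request at desk-scale depths to exercise the
interval assigner; at full depth count tables are drawn directly.

What the generator does **not** emulate: spliced/junction reads,
positional or GC bias, paired-end fragment structure, overlapping gene
loci, multimapping, isoform switching, incomplete or delayed
transcription shutoff, and reference-gene instability. Passing tests
therefore demonstrate the correctness of the statistical machinery under
the stated kinetic model, not robustness to every artifact of real
libraries.

## Problem sizes and numerical choices

Tests and the acceptance script run the standard designs: 200 noiseless
and 1,000 noisy genes for decay recovery (noisy series use half-lives in
[4, 50] h with expected t = 0 counts of 2,000, keeping every time
point's expectation ≥ 500), the 300-gene study for attribution, and a
20-gene hand-built fixture for the filter-attrition oracle. These sizes
make every property check run in seconds while keeping counting noise in
the regime where the thresholds are meaningfully exercised.

Determinism: all randomness flows through numpy `Generator`s seeded from
the configuration; each generator stage draws from its own named stream
so outputs are reproducible independently of call order, and a fixed
seed yields byte-identical output files.

## Known limitations

* Single-interval, unstranded read model; no BAM input (counts or BED).
* One-phase exponential decay only; no confidence intervals on
  half-lives.
* No significance testing on fold changes — classes are pure ratio
  thresholds on condition means, by design.
* Enrichment reproduces the test, not any specific annotation service's
  curated term database.
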