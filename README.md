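# mrnafate

Transcript-fate analysis for two-condition bulk RNA-seq studies: decide,
gene by gene, whether an expression change is driven by altered **mRNA
stability** or by altered **transcription**.

The motivating setting is a conditional knockout of an mRNA-decay factor
(e.g. the scaffold of the CCR4–NOT deadenylase complex in adipose
tissue), where the naive expectation — "loss of decay stabilizes mRNAs,
so everything that goes up does so because it decays more slowly" — can
be wrong: transcriptional rewiring may dominate. Telling the two apart
requires measuring three layers per gene and condition:

1. **mature mRNA** — exonic FPKM, normalized to the *Gapdh* internal
   control:
   `FPKM_g = c_g · 10⁹ / (L_g · C)` with `c_g` exonic reads, `L_g` the
   exon-union length, `C` the sample's total exonic reads; expression
   value = `FPKM_g / FPKM_Gapdh`.
2. **mRNA stability** — half-lives from a transcription-shutoff
   (actinomycin D) chase at 0/4/8 h. Per gene and condition, relative
   expression `y(t)/y(0)` is fit by OLS on the natural-log scale and
   `t½ = (ln 0.5 − β₀)/β₁` (intercept `β₀`, slope `β₁`); fits outside
   [0, 50] h or from genes below 0.1 FPKM are excluded.
3. **transcription** — intronic FPKM (iFPKM), the same density formula
   restricted to intronic reads and summed intron length; pre-mRNA
   abundance is a standard proxy for transcription rate.

Classes use pure ratio thresholds on condition means (KO/control):
up `> 2.0` (configurable to `2.5`), down `< 0.5`; stabilized `t½` ratio
`> 2.0`, destabilized `< 0.5`. A changed mRNA with a concordant
stability change and quiet pre-mRNA is *stability-driven*; a concordant
pre-mRNA change with unchanged stability is *transcription-driven*
(plus `both` / `discordant` / `unexplained`). Classified gene lists can
be tested for gene-set overrepresentation (hypergeometric upper tail,
Benjamini–Hochberg FDR, shortlist of ≤ 6 terms below FDR 0.05), and a
ΔΔCt module covers qPCR validation
(`fold = 2^−ΔΔCt` against *Gapdh* and the control group).

A first-class synthetic-data generator produces annotation, counts,
chase time courses and gene sets from known per-gene transcription rates
and half-lives (steady state = rate × t½ / ln 2, Poisson counts), so
every stage is verifiable against ground truth at desk scale.

## Worked example

```python
from mrnafate import (
    SimConfig, simulate_dataset, quantify_counts, fpkm_table,
    normalize_to_reference, fit_decay_table, filter_half_lives,
    stability_table, fold_change, attribute_table,
)
from mrnafate.synthetic import attribution_accuracy

sim = simulate_dataset(SimConfig(seed=17))          # 300 genes, 4 replicates
expr = quantify_counts(sim.steady_counts, sim.models, sim.steady_samples)
chase = normalize_to_reference(fpkm_table(sim.chase_counts, sim.models))
fits = filter_half_lives(fit_decay_table(chase, sim.chase_samples))
stability = stability_table(fits)
fc_m = fold_change(expr, sim.steady_samples, "mRNA")
fc_p = fold_change(expr, sim.steady_samples, "pre-mRNA")
attribution = attribute_table(fc_m, fc_p, stability)
print(stability.klass.value_counts().to_dict())
print(attribution.driver.value_counts().to_dict())
print(f"{attribution_accuracy(sim.truth, attribution):.1%}")
```

prints

```
{'unchanged': 239, 'stabilized': 30, 'destabilized': 30}
{'stability': 60, 'transcription': 60}
100.0%
```

i.e. the 30 genes designed stabilized (half-life × 4 in the knockout)
and 30 destabilized (× 0.25) are all recovered as stability-driven
expression changes, the 60 transcriptionally perturbed genes as
transcription-driven, and no null gene is misclassified. The median
relative error of the recovered control half-lives on this dataset is
0.7 % (see `examples/03_half_lives.py`).

The `examples/` directory holds one short script per capability
(simulation, quantification, half-lives, attribution, enrichment, ΔΔCt,
full pipeline); each prints its numbers and what they mean. The same
stages are available from the shell via the thin `mrnafate` CLI
(`simulate`, `quantify`, `decay`, `classify`, `enrich`, `ddct`, and
`run --config run.yaml` for the end-to-end pipeline with a markdown
report and filter-attrition funnel).

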