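"""Synthetic transcript-fate data with known per-gene ground truth.

The generator emulates the measurement structure of a two-condition
(control vs. knockout) adipose RNA-seq study: steady-state exonic and
intronic read counts across replicates, and transcription-shutoff chase
time courses at 0/4/8 h, all driven by a minimal kinetic model per gene:

    steady-state abundance = transcription_rate x half_life / ln 2

Exonic read expectations track abundance x exon-union length; intronic
read expectations track transcription rate x intron length (pre-mRNA as a
transcription proxy — intronic signal follows the synthesis rate, not the
mature-mRNA pool).  Chase expectations decay as 2^(-t / half_life) from
the steady state, with transcription shut off completely and instantly.
Counts are Poisson by default (optional gamma overdispersion).

Designed gene classes (stabilized / destabilized / transcription_up /
transcription_down) perturb exactly one kinetic parameter in the knockout
by a configurable effect ratio (default 4.0 up, 0.25 down).  Designed
genes always carry at least two exons and >=150 bp of intron so that every
effect is in principle recoverable through the standard filters; null
genes include the degenerate geometry (single-exon genes, sub-150 bp
introns) and a few non-coding biotypes that those filters must remove.
A Gapdh gene is planted as the internal control: identical parameters in
both conditions and an effectively infinite half-life (1e6 h), so
Gapdh-normalized chase values carry the absolute decay signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneModel, GenomicInterval, build_gene_model, write_gtf
from .enrich import GeneSet, write_gmt

__all__ = ["SimConfig", "SimData", "simulate_truth", "simulate_annotation",
           "simulate_steady_counts", "simulate_reads_bed", "simulate_chase",
           "simulate_gene_sets", "simulate_dataset", "write_dataset"]

LN2 = np.log(2.0)

GAPDH_ID = "Gapdh"
GAPDH_HALF_LIFE_H = 1e6  # effectively stable over an 8 h chase
GAPDH_ABUNDANCE = 500.0

DESIGNED_CLASSES = (
    "stabilized",
    "destabilized",
    "transcription_up",
    "transcription_down",
)

# fixed per-purpose RNG streams so each stage is reproducible on its own
_STREAMS = {"truth": 1, "annotation": 2, "steady": 3, "chase": 4, "sets": 5, "reads": 6}


@dataclass
class SimConfig:
    """Study-design knobs for the generator.

    Defaults mirror the emulated study: two conditions x 4 replicates,
    chase at 0/4/8 h, 300 genes, 3e6 reads per sample, effect ratios 4.0
    (up/stabilized) and 0.25 (down/destabilized).
    """

    n_genes: int = 300
    fractions: dict = field(
        default_factory=lambda: {
            "stabilized": 0.10,
            "destabilized": 0.10,
            "transcription_up": 0.10,
            "transcription_down": 0.10,
        }
    )
    effect_ratio_up: float = 4.0
    effect_ratio_down: float = 0.25
    replicates: int = 4
    chase_time_points_h: tuple = (0.0, 4.0, 8.0)
    depth: float = 3e6  # reads per steady-state sample
    chase_depth: float = 3e6  # reads per chase sample
    intron_read_fraction: float = 0.10
    read_length: int = 80
    noncoding_fraction: float = 0.05  # of null genes
    conditions: tuple = ("control", "KO")
    tissue: str = "iWAT"
    half_life_range_h: tuple = (2.0, 10.0)
    rate_lognorm_mu: float = np.log(10.0)
    rate_lognorm_sigma: float = 1.0
    poisson_noise: bool = True
    dispersion: float | None = None  # gamma overdispersion; None = pure Poisson
    seed: int = 17

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % (2**31), _STREAMS[stream]])

    def __post_init__(self) -> None:
        if sum(self.fractions.values()) > 1:
            raise ValueError("designed-class fractions must sum to <= 1")
        unknown = set(self.fractions) - set(DESIGNED_CLASSES)
        if unknown:
            raise ValueError(f"unknown designed classes: {sorted(unknown)}")


@dataclass
class SimData:
    """Everything one simulated study produces, with ground truth attached."""

    config: SimConfig
    truth: pd.DataFrame
    models: dict[str, GeneModel]
    steady_counts: pd.DataFrame
    steady_samples: pd.DataFrame
    steady_expected: pd.DataFrame
    chase_counts: pd.DataFrame
    chase_samples: pd.DataFrame
    gene_sets: list[GeneSet]


def simulate_truth(config: SimConfig) -> pd.DataFrame:
    """Assign designed classes and per-condition kinetic parameters.

    Returns one row per gene: designed_class, transcription rate and
    half-life per condition, and the implied steady-state abundance
    (rate x half-life / ln 2).
    """
    rng = config.rng("truth")
    n = config.n_genes
    if n < 2:
        raise ValueError("need at least 2 genes (one is the Gapdh control)")
    classes = ["reference"]  # Gapdh, unperturbed by construction
    for klass in DESIGNED_CLASSES:
        classes += [klass] * int(round(config.fractions.get(klass, 0) * n))
    classes = classes[:n]
    classes += ["null"] * (n - len(classes))

    gene_ids = [GAPDH_ID] + [f"G{i:04d}" for i in range(1, n)]
    hl_lo, hl_hi = config.half_life_range_h
    hl = np.exp(rng.uniform(np.log(hl_lo), np.log(hl_hi), size=n))
    rate = np.exp(rng.normal(config.rate_lognorm_mu, config.rate_lognorm_sigma, size=n))

    rows = []
    for gid, klass, h, r in zip(gene_ids, classes, hl, rate):
        hc, hk, rc, rk = h, h, r, r
        if klass == "stabilized":
            hk = h * config.effect_ratio_up
        elif klass == "destabilized":
            hk = h * config.effect_ratio_down
        elif klass == "transcription_up":
            rk = r * config.effect_ratio_up
        elif klass == "transcription_down":
            rk = r * config.effect_ratio_down
        elif klass == "reference":
            hc = hk = GAPDH_HALF_LIFE_H
            rc = rk = GAPDH_ABUNDANCE * LN2 / GAPDH_HALF_LIFE_H
        rows.append(
            {
                "gene_id": gid,
                "designed_class": "null" if klass == "reference" else klass,
                "rate_control": rc,
                "rate_ko": rk,
                "half_life_control": hc,
                "half_life_ko": hk,
                "abundance_control": rc * hc / LN2,
                "abundance_ko": rk * hk / LN2,
            }
        )
    return pd.DataFrame(rows)


def simulate_annotation(
    config: SimConfig, truth: pd.DataFrame | None = None
) -> dict[str, GeneModel]:
    """Build non-overlapping gene models on synthetic chromosomes.

    Null genes get 1-12 exons (80-3000 bp) and intron lengths 60-10,000 bp
    — so single-exon genes and sub-150 bp intron sums occur by design.
    Designed genes get 2-12 exons with introns of 200-10,000 bp.  A few
    null genes are non-coding.  Gapdh gets a typical 8-exon structure.
    """
    if truth is None:
        truth = simulate_truth(config)
    rng = config.rng("annotation")
    models: dict[str, GeneModel] = {}
    genes_per_chrom = 50
    pos, chrom_i = 1000, 1
    noncoding_draw = rng.random(len(truth))
    for i, rec in enumerate(truth.itertuples(index=False)):
        designed = rec.designed_class != "null" or rec.gene_id == GAPDH_ID
        if rec.gene_id == GAPDH_ID:
            n_exons = 8
        elif designed:
            n_exons = int(rng.integers(2, 13))
        else:
            n_exons = int(rng.integers(1, 13))
        exon_lens = rng.integers(80, 3001, size=n_exons)
        intron_lo = 200 if designed else 60
        intron_lens = rng.integers(intron_lo, 10001, size=max(n_exons - 1, 0))
        chrom = f"chr{chrom_i}"
        exons, cursor = [], pos
        for j, el in enumerate(exon_lens):
            exons.append(GenomicInterval(chrom, cursor, cursor + int(el)))
            if j < len(intron_lens):
                cursor += int(el) + int(intron_lens[j])
            else:
                cursor += int(el)
        biotype = "protein_coding"
        if not designed and noncoding_draw[i] < config.noncoding_fraction:
            biotype = "lincRNA"
        strand = "+" if rng.random() < 0.5 else "-"
        models[rec.gene_id] = build_gene_model(
            rec.gene_id,
            exons,
            strand=strand,
            biotype=biotype,
            gene_name=rec.gene_id,
        )
        pos = cursor + int(rng.integers(500, 5001))
        if (i + 1) % genes_per_chrom == 0:
            chrom_i += 1
            pos = 1000
    return models


def _draw_counts(
    rng: np.random.Generator, lam: np.ndarray, config: SimConfig
) -> np.ndarray:
    lam = np.asarray(lam, dtype=float)
    if not config.poisson_noise:
        return lam
    if config.dispersion:
        # gamma-Poisson mixture: var = lam + dispersion * lam^2
        shape = 1.0 / config.dispersion
        lam = rng.gamma(shape, lam * config.dispersion)
    return rng.poisson(lam).astype(float)


def _steady_sample_sheet(config: SimConfig) -> pd.DataFrame:
    rows = [
        {
            "sample_id": f"{cond}_{config.tissue}_r{r}",
            "condition": cond,
            "tissue": config.tissue,
            "replicate": r,
            "time_point_h": np.nan,
        }
        for cond in config.conditions
        for r in range(1, config.replicates + 1)
    ]
    return pd.DataFrame(rows)


def simulate_steady_counts(
    models: dict[str, GeneModel], truth: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Steady-state exonic/intronic counts for every sample.

    Exonic expectation per gene is proportional to abundance x exon-union
    length; intronic expectation to transcription rate x intron length.
    The intronic compartment receives ``intron_read_fraction`` of the
    depth.  Returns (counts, samples, expected) — ``expected`` carries the
    per-condition Poisson means for verification.
    """
    rng = config.rng("steady")
    samples = _steady_sample_sheet(config)
    gene_ids = list(truth["gene_id"])
    exon_len = np.array([models[g].exon_union_length for g in gene_ids], float)
    intron_len = np.array([models[g].intron_length_sum for g in gene_ids], float)

    cond_key = {"control": ("abundance_control", "rate_control"),
                "KO": ("abundance_ko", "rate_ko")}
    expected_rows, count_rows = [], []
    lam_by_cond = {}
    for cond in config.conditions:
        ab_col, rate_col = cond_key[cond]
        w_ex = truth[ab_col].to_numpy() * exon_len
        w_in = truth[rate_col].to_numpy() * intron_len
        lam_ex = config.depth * (1 - config.intron_read_fraction) * w_ex / w_ex.sum()
        lam_in = (
            config.depth * config.intron_read_fraction * w_in / w_in.sum()
            if w_in.sum() > 0
            else np.zeros_like(w_in)
        )
        lam_by_cond[cond] = (lam_ex, lam_in)
        expected_rows.append(
            pd.DataFrame(
                {
                    "gene_id": gene_ids,
                    "condition": cond,
                    "expected_exonic": lam_ex,
                    "expected_intronic": lam_in,
                }
            )
        )
    for rec in samples.itertuples(index=False):
        lam_ex, lam_in = lam_by_cond[rec.condition]
        ex = _draw_counts(rng, lam_ex, config)
        inn = _draw_counts(rng, lam_in, config)
        count_rows.append(
            pd.DataFrame(
                {
                    "gene_id": gene_ids,
                    "sample_id": rec.sample_id,
                    "exonic_count": ex,
                    "intronic_count": inn,
                }
            )
        )
    counts = pd.concat(count_rows, ignore_index=True)
    if config.poisson_noise:
        counts[["exonic_count", "intronic_count"]] = counts[
            ["exonic_count", "intronic_count"]
        ].astype(int)
    return counts, samples, pd.concat(expected_rows, ignore_index=True)


def simulate_reads_bed(
    counts: pd.DataFrame, models: dict[str, GeneModel], config: SimConfig
) -> pd.DataFrame:
    """Place each counted read uniformly inside one exon or intron.

    Reads are single intervals contained in a single exon (exonic) or a
    single intron (intronic), so the built-in assigner can reconstruct the
    count table exactly on non-overlapping gene models.  Intended for
    desk-scale depths; at full depth use the count table directly.
    """
    rng = config.rng("reads")
    rows = []
    for rec in counts.itertuples(index=False):
        gm = models[rec.gene_id]
        for compartment, n in (("exon", int(rec.exonic_count)),
                               ("intron", int(rec.intronic_count))):
            ivs = gm.exons if compartment == "exon" else gm.introns
            if n == 0 or not ivs:
                continue
            lens = np.array([iv.length for iv in ivs], float)
            picks = rng.choice(len(ivs), size=n, p=lens / lens.sum())
            for p in picks:
                iv = ivs[p]
                rlen = min(config.read_length, iv.length)
                start = int(rng.integers(iv.start, iv.end - rlen + 1))
                rows.append((gm.chrom, start, start + rlen, rec.sample_id))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "sample_id"])


def simulate_chase(
    models: dict[str, GeneModel], truth: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shutoff-chase exonic counts per condition, replicate and time point.

    Expected abundance decays as abundance(0) x 2^(-t/half_life); the read
    share of each gene follows abundance(t) x exon length within each
    sample (sequencing depth per sample is constant, so the global decay
    is only visible relative to the stable Gapdh control).  Intronic
    counts are zero: transcription is assumed fully and instantly shut
    off.
    """
    rng = config.rng("chase")
    gene_ids = list(truth["gene_id"])
    exon_len = np.array([models[g].exon_union_length for g in gene_ids], float)
    cond_key = {"control": ("abundance_control", "half_life_control"),
                "KO": ("abundance_ko", "half_life_ko")}
    sample_rows, count_rows = [], []
    for cond in config.conditions:
        ab_col, hl_col = cond_key[cond]
        a0 = truth[ab_col].to_numpy()
        hl = truth[hl_col].to_numpy()
        for t in config.chase_time_points_h:
            w = a0 * np.power(2.0, -t / hl) * exon_len
            lam = config.chase_depth * w / w.sum()
            for r in range(1, config.replicates + 1):
                sid = f"{cond}_t{t:g}_r{r}"
                sample_rows.append(
                    {
                        "sample_id": sid,
                        "condition": cond,
                        "tissue": config.tissue,
                        "replicate": r,
                        "time_point_h": float(t),
                    }
                )
                ex = _draw_counts(rng, lam, config)
                count_rows.append(
                    pd.DataFrame(
                        {
                            "gene_id": gene_ids,
                            "sample_id": sid,
                            "exonic_count": ex,
                            "intronic_count": 0.0,
                        }
                    )
                )
    counts = pd.concat(count_rows, ignore_index=True)
    if config.poisson_noise:
        counts[["exonic_count", "intronic_count"]] = counts[
            ["exonic_count", "intronic_count"]
        ].astype(int)
    return counts, pd.DataFrame(sample_rows)


def simulate_decay_series(
    n_genes: int,
    seed: int,
    mean_count_t0: float = 2000.0,
    half_life_range_h: tuple = (4.0, 50.0),
    time_points_h: tuple = (0.0, 4.0, 8.0),
    poisson_noise: bool = True,
) -> pd.DataFrame:
    """Standalone per-gene chase series for decay-recovery experiments.

    Each gene gets a log-uniform true half-life and expected counts
    mean_count_t0 x 2^(-t/half_life) at each time point (Poisson-sampled
    unless disabled).  The default range and depth keep the expected count
    at every time point at or above mean_count_t0 / 4 (>= 500 at the
    default depth).  Long format: gene_id, true_half_life_h,
    time_point_h, count.
    """
    rng = np.random.default_rng(seed)
    lo, hi = half_life_range_h
    hls = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_genes))
    rows = []
    for i, hl in enumerate(hls):
        for t in time_points_h:
            lam = mean_count_t0 * 2.0 ** (-t / hl)
            count = float(rng.poisson(lam)) if poisson_noise else lam
            rows.append(
                {
                    "gene_id": f"G{i:04d}",
                    "true_half_life_h": hl,
                    "time_point_h": t,
                    "count": count,
                }
            )
    return pd.DataFrame(rows)


def simulate_gene_sets(
    truth: pd.DataFrame, config: SimConfig, n_decoys: int = 20
) -> list[GeneSet]:
    """One planted term per non-empty designed class plus random decoys.

    Each planted term holds 80% of its class's genes diluted with an equal
    number of random null genes, so the class query list should rank it
    first; decoy terms are random draws from all genes.
    """
    rng = config.rng("sets")
    null_genes = list(truth.loc[truth["designed_class"] == "null", "gene_id"])
    all_genes = list(truth["gene_id"])
    sets: list[GeneSet] = []
    for klass in DESIGNED_CLASSES:
        members = list(truth.loc[truth["designed_class"] == klass, "gene_id"])
        if not members:
            continue
        n_core = max(int(round(0.8 * len(members))), 1)
        core = list(rng.choice(members, size=n_core, replace=False))
        n_pad = min(len(core), len(null_genes))
        pad = list(rng.choice(null_genes, size=n_pad, replace=False))
        sets.append(GeneSet(f"SET_{klass.upper()}", f"planted {klass} set",
                            set(core) | set(pad)))
    for d in range(n_decoys):
        size = int(rng.integers(10, 51))
        members = set(rng.choice(all_genes, size=min(size, len(all_genes)),
                                 replace=False))
        sets.append(GeneSet(f"DECOY_{d:03d}", f"random decoy {d}", members))
    return sets


EXPECTED_DRIVER = {
    "stabilized": ("up", "stability"),
    "destabilized": ("down", "stability"),
    "transcription_up": ("up", "transcription"),
    "transcription_down": ("down", "transcription"),
}


def attribution_accuracy(truth: pd.DataFrame, attribution: pd.DataFrame) -> float:
    """Fraction of designed (non-null) genes whose recovered expression
    class and attributed driver match the designed effect."""
    att = attribution.set_index("gene_id")
    designed = truth[truth["designed_class"] != "null"]
    if designed.empty:
        raise ValueError("truth table contains no designed genes")
    hits = 0
    for rec in designed.itertuples(index=False):
        want = EXPECTED_DRIVER[rec.designed_class]
        if rec.gene_id in att.index:
            row = att.loc[rec.gene_id]
            if (row["expr_klass"], row["driver"]) == want:
                hits += 1
    return hits / len(designed)


def simulate_dataset(config: SimConfig | None = None, **overrides) -> SimData:
    """Run the whole generator with one config; the one-stop entry point."""
    if config is None:
        config = SimConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    truth = simulate_truth(config)
    models = simulate_annotation(config, truth)
    steady_counts, steady_samples, expected = simulate_steady_counts(
        models, truth, config
    )
    chase_counts, chase_samples = simulate_chase(models, truth, config)
    sets = simulate_gene_sets(truth, config)
    return SimData(
        config=config,
        truth=truth,
        models=models,
        steady_counts=steady_counts,
        steady_samples=steady_samples,
        steady_expected=expected,
        chase_counts=chase_counts,
        chase_samples=chase_samples,
        gene_sets=sets,
    )


def write_dataset(sim: SimData, out_dir: str | Path, emit_bed: bool = False) -> dict:
    """Write genes.gtf, counts, sample sheets, truth and sets.gmt to disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation": out / "genes.gtf",
        "truth": out / "truth.tsv",
        "steady_counts": out / "steady_counts.tsv",
        "steady_samples": out / "steady_samples.tsv",
        "chase_counts": out / "chase_counts.tsv",
        "chase_samples": out / "chase_samples.tsv",
        "gene_sets": out / "sets.gmt",
    }
    write_gtf(sim.models.values(), paths["annotation"])
    sim.truth.to_csv(paths["truth"], sep="\t", index=False)
    sim.steady_counts.to_csv(paths["steady_counts"], sep="\t", index=False)
    sim.steady_samples.to_csv(paths["steady_samples"], sep="\t", index=False)
    sim.chase_counts.to_csv(paths["chase_counts"], sep="\t", index=False)
    sim.chase_samples.to_csv(paths["chase_samples"], sep="\t", index=False)
    write_gmt(sim.gene_sets, paths["gene_sets"])
    if emit_bed:
        bed = simulate_reads_bed(sim.steady_counts, sim.models, sim.config)
        paths["reads"] = out / "reads.bed"
        bed.to_csv(paths["reads"], sep="\t", index=False, header=False)
    return {k: str(v) for k, v in paths.items()}
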