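import pandas as pd
import pytest

from mrnafate import decay, diffexpr, quantify
from mrnafate.synthetic import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_sim():
    """The default study design: 300 genes, 4 replicates, depth 3e6, seed 17."""
    return simulate_dataset(SimConfig(seed=17))


@pytest.fixture(scope="session")
def small_sim():
    """A desk-scale dataset cheap enough for per-read and I/O tests."""
    return simulate_dataset(
        SimConfig(seed=3, n_genes=50, depth=20000, chase_depth=20000, replicates=2)
    )


@pytest.fixture(scope="session")
def default_analysis(default_sim):
    """Full analysis products on the default simulation."""
    sim = default_sim
    expr = quantify.quantify_counts(sim.steady_counts, sim.models, sim.steady_samples)
    chase_expr = quantify.normalize_to_reference(
        quantify.fpkm_table(sim.chase_counts, sim.models)
    )
    fits = decay.filter_half_lives(decay.fit_decay_table(chase_expr, sim.chase_samples))
    stability = decay.stability_table(fits)
    fc_mrna = diffexpr.fold_change(expr, sim.steady_samples, "mRNA")
    fc_pre = diffexpr.fold_change(expr, sim.steady_samples, "pre-mRNA")
    attribution = diffexpr.attribute_table(fc_mrna, fc_pre, stability)
    return {
        "sim": sim,
        "expr": expr,
        "fits": fits,
        "stability": stability,
        "fc_mrna": fc_mrna,
        "fc_pre": fc_pre,
        "attribution": attribution,
    }


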