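import numpy as np
import pandas as pd
import pytest

from cardioscreen import synthetic_data as synth


@pytest.fixture(scope="session")
def small_null_screen() -> pd.DataFrame:
    """A 200-gene screen with no spiked effects (fixed seed)."""
    lib = synth.generate_library(200, shrna_count_sampler=6, seed=101)
    cfg = synth.SimulationConfig(seed=102, depth=240_000, dispersion=0.1, n_genes=200)
    return synth.simulate_shrna_counts(lib, [], cfg)


@pytest.fixture(scope="session")
def spiked_screen() -> tuple[pd.DataFrame, list[str], list[str]]:
    """A 120-gene screen with 8 enriched and 8 depleted genes at 4-fold."""
    lib = synth.generate_library(120, shrna_count_sampler=6, seed=201)
    genes = lib.genes
    rng = np.random.default_rng(202)
    spiked = list(rng.choice(genes, size=16, replace=False))
    effects = [synth.EffectSpec(g, "enriched", 4.0) for g in spiked[:8]]
    effects += [synth.EffectSpec(g, "depleted", 0.25) for g in spiked[8:]]
    cfg = synth.SimulationConfig(seed=203, depth=150_000, dispersion=0.1, n_genes=120)
    return synth.simulate_shrna_counts(lib, effects, cfg), spiked[:8], spiked[8:]
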