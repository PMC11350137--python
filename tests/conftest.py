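import numpy as np
import pandas as pd
import pytest

from crossgain.gmap import GeneticMap
from crossgain.simnam import SimConfig, simulate_nam


@pytest.fixture
def small_map():
    return GeneticMap.uniform(2, 6, 80.0)


@pytest.fixture(scope="session")
def tiny_nam():
    """Small two-trait NAM used by several module tests (read-only)."""
    cfg = SimConfig(
        n_founders=5, n_families=5, ril_per_family=40,
        n_chromosomes=3, markers_per_chromosome=12, chromosome_length_cM=90.0,
        n_qtl=18, heritability=(0.8, 0.8), effect_correlations=(0.6,),
        n_environments=3, env_variance=1.0, rng_seed=7,
    )
    return simulate_nam(cfg)


def balanced_phenos(q, r, s2g, s2t, s2e, rng, trait="tr", mu=10.0,
                    family="f1"):
    """Balanced genotype x environment plot table with known components."""
    g = rng.normal(0.0, np.sqrt(s2g), q)
    t = rng.normal(0.0, np.sqrt(s2t), r)
    rows = []
    for i in range(q):
        for j in range(r):
            rows.append((f"g{i:03d}", f"e{j}", trait,
                         mu + g[i] + t[j] + rng.normal(0.0, np.sqrt(s2e))))
    df = pd.DataFrame(rows, columns=["line_id", "env_id", "trait", "value"])
    df["family_id"] = family
    return df
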