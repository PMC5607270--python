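import numpy as np
import pandas as pd
import pytest

from crossase.simulate import (SimConfig, simulate_f1_counts,
                               simulate_parental_vcfs)


@pytest.fixture(scope="session")
def cis_sim():
    """Moderate simulation with line-of-origin (cis) effects and no
    imprinting; shared across tests that only read from it."""
    cfg = SimConfig(seed=11, n_loci=1500, n_genes=300, frac_cis_ase=0.15,
                    cis_effect=0.7, depth_mean=100.0, error_rate=0.0)
    sim = simulate_parental_vcfs(cfg)
    obs = simulate_f1_counts(cfg, sim.truth)
    return cfg, sim, obs


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_obs(rows, **common):
    """Build a minimal allelic-observation table for filter fixtures."""
    defaults = dict(sample="S1", cross="FL", tissue="brain", chrom="1",
                    GQ=80, QD=20.0, FS=1.0)
    defaults.update(common)
    records = []
    for row in rows:
        rec = dict(defaults)
        rec.update(row)
        rec.setdefault("DP", rec.get("ref_count", 0) + rec.get("alt_count", 0))
        records.append(rec)
    return pd.DataFrame(records)


@pytest.fixture
def obs_builder():
    return make_obs
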