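import numpy as np
import pandas as pd
import pytest

import methylpurity as mp


@pytest.fixture
def small_beta() -> mp.BetaMatrix:
    df = pd.DataFrame(
        {
            "T1": [0.1, 0.9, 0.5],
            "T2": [0.2, 0.8, 0.5],
        },
        index=["cg1", "cg2", "cg3"],
    )
    return mp.BetaMatrix(df)


@pytest.fixture(scope="session")
def idmc_grade_dataset():
    """1000 marker-grade DMC sites, 50 tumors with dispersed purity."""
    cfg = mp.idmc_grade_config(n_sites=1000, frac_dmc=1.0, n_tumor=50, n_normal=20, seed=11)
    return mp.generate(cfg)


@pytest.fixture(scope="session")
def dm_dataset():
    """10% true DMCs (transformed-scale effect 0.5), n0 = n1 = 30."""
    cfg = mp.SynthConfig(
        n_sites=5000, n_tumor=30, n_normal=30, frac_dmc=0.1, effect_mean=0.5, seed=12
    )
    return mp.generate(cfg)


@pytest.fixture(scope="session")
def null_dataset():
    """No true DMCs anywhere; 5000 sites, n0 = n1 = 30."""
    cfg = mp.SynthConfig(n_sites=5000, n_tumor=30, n_normal=30, frac_dmc=0.0, seed=13)
    return mp.generate(cfg)


@pytest.fixture(scope="session")
def controlfree_dataset():
    """50 tumors, lambda ~ U(0.2, 0.95), 10% DMCs with effect 0.5."""
    cfg = mp.SynthConfig(
        n_sites=2000,
        n_tumor=50,
        n_normal=0,
        frac_dmc=0.1,
        effect_mean=0.5,
        purity_low=0.2,
        purity_high=0.95,
        seed=14,
    )
    return mp.generate(cfg)


def truth_labels(result: pd.DataFrame, truth: mp.SynthTruth) -> np.ndarray:
    """is_dmc truth aligned to a result table's site order."""
    return (
        truth.sites.set_index("site_id").loc[result["site_id"], "is_dmc"].to_numpy()
    )
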