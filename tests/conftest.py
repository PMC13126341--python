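import numpy as np
import pandas as pd
import pytest

from mrchain.models import HarmonizedPair


def make_pairs(bx, sx, by, sy, ids=None):
    """Hand-build harmonized pairs from parallel arrays."""
    k = len(bx)
    ids = ids if ids is not None else [f"rs{i}" for i in range(k)]
    return [
        HarmonizedPair(
            snp_id=ids[i], beta_exp=bx[i], se_exp=sx[i], beta_out=by[i], se_out=sy[i]
        )
        for i in range(k)
    ]


@pytest.fixture
def toy_pairs():
    """Three hand-set instruments, heterogeneous enough to exercise SEs."""
    return make_pairs(
        bx=[0.5, 0.4, 0.3], sx=[0.02, 0.02, 0.03], by=[0.10, 0.09, 0.05], sy=[0.05, 0.04, 0.06]
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small but realistic three-trait simulation shared across tests."""
    from mrchain.simulate import SimulationConfig, simulate_cohort

    cfg = SimulationConfig(
        n_snps=30, n_exposure=2000, n_mediator=2000, n_outcome=2000, seed=11
    )
    exposure, mediator, outcome, truth = simulate_cohort(cfg)
    return cfg, exposure, mediator, outcome, truth
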