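"""Shared fixtures: published truth parameter sets and synthetic series."""

import numpy as np
import pytest

import fivehit as fh


@pytest.fixture(scope="session")
def table1_seq():
    return fh.MutationSequence.from_id("K,A1,A2,T1,T2")


@pytest.fixture(scope="session")
def table1_params(table1_seq):
    truth = fh.fitted_for("K,A1,A2,T1,T2")
    return fh.build_model_parameters(table1_seq, truth.theta, N=1e8, Tlag=5.0)


@pytest.fixture(scope="session")
def table1_series(table1_seq, table1_params):
    """Noise-free incidence series generated from the KRAS-first fit."""
    cfg = fh.SyntheticConfig(
        truth=table1_params,
        pathway=table1_seq,
        ages=np.arange(85.0),
        noise="none",
        fraction_triple_mutant=1.0,
        seed=0,
    )
    return fh.generate(cfg)


#: down-scaled parameter set for stochastic-oracle comparisons: small cell
#: pool, inflated influx and stage rates, modest division/death rates
@pytest.fixture(scope="session")
def oracle_params():
    return fh.ModelParameters(
        N=1e3,
        muN=4e-3,
        mu=(9e-3,) * 4,
        alpha=(0.35, 0.40, 0.45, 0.50),
        beta=(0.25,) * 4,
        Tlag=0.0,
    )


@pytest.fixture(scope="session")
def oracle_tau_sample(oracle_params):
    """10^4 first-malignancy times at the down-scaled oracle parameters."""
    return fh.first_hit_times(oracle_params, reps=10_000, seed=20240, t_max=32.0)
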