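"""Shared fixtures.

The expensive full-scale study (five naturalistic simulations plus the
double-strength arm, with network statistics) is built once per session
and shared by the acceptance tests; everything else runs on small
networks built per test.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from recruitnet.params import (ConnectivityParams, NeuronParams,
                               SimulationConfig)
from recruitnet.pipeline import ExperimentConfig, run_full_study
from recruitnet.simulate import excitatory_raster, run_session

SESSION_SEED = 301


@pytest.fixture(scope="session")
def study():
    """Full-scale study: 5 naturalistic + 5 paired double-strength runs."""
    cfg = ExperimentConfig(
        n_naturalistic=5, n_double=5, n_null=8, base_seed=SESSION_SEED,
        n_coincidence_triplets=20000)
    report = run_full_study(cfg)
    assert not report.partial, report.failures
    return report


@pytest.fixture(scope="session")
def long_protocol_raster():
    """Free-evolution protocol: 50 ms input then 950 ms recorded."""
    from recruitnet.network import build_synaptic_network

    conn = ConnectivityParams()
    net = build_synaptic_network(conn, rng_seed=SESSION_SEED)
    cfg = SimulationConfig(seed=SESSION_SEED, input_duration=50.0,
                           record_duration=950.0, trials_per_epoch=100,
                           n_epochs=1)
    raster, _ = run_session(net, NeuronParams(), cfg)
    return excitatory_raster(net, raster)


@pytest.fixture(scope="session")
def small_sim():
    """A small but active network simulation for unit-level checks.

    Small networks at the full-scale 5:1 E:I ratio fall into the
    saturated runaway state; a relatively larger inhibitory population
    keeps this fixture in the sparse regime.
    """
    from recruitnet.network import build_synaptic_network

    conn = ConnectivityParams(N_e=160, N_i=48, N_input=16)
    net = build_synaptic_network(conn, rng_seed=5)
    cfg = SimulationConfig(seed=5, trials_per_epoch=10, n_epochs=2)
    raster, _ = run_session(net, NeuronParams(), cfg)
    return net, cfg, raster
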