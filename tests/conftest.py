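"""Shared fixtures: cached integrate-and-fire recordings and model fits.

The expensive artifacts (simulated critical/off-critical recordings and
their Boltzmann-machine fits) are produced once per session and shared
across test modules.  Sizes are the package's reduced study conditions
(5e5 bins, ~3.5e3 learning iterations); docs/methods.md discusses what
they do and do not probe.
"""

from __future__ import annotations

import numpy as np
import pytest

from neuromaxent.ifnet import (DynamicsParams, build_network,
                               delta_u_rec_for_state, pretrain, run_recording)
from neuromaxent.maxent import LearningSchedule, SamplerConfig, bm_fit
from neuromaxent.spike_stats import bin_events, compute_moments

N_BINS = 500_000
BIN_WIDTH = 5


def scaled_schedule(n: int) -> LearningSchedule:
    """Reduced-size learning schedule used throughout the test suite."""
    mc = {True: 40_000, False: 60_000}[n <= 20]
    return LearningSchedule(theta0=0.3, alpha=0.5, max_iters=3500,
                            mc_samples=mc, vk_rate_switch_iter=1000)


def simulate(state: str, n: int, rep: int = 0):
    """One pre-trained recording of the IF network in a named state."""
    params = DynamicsParams(delta_u_rec=delta_u_rec_for_state(n, state))
    topo = build_network(n, params, seed=100 * n + rep)
    topo = pretrain(topo, params, seed=200 * n + rep)
    return run_recording(topo, params, n_timesteps=N_BINS * BIN_WIDTH,
                         seed=300 * n + rep, warmup_avalanches=2000)


@pytest.fixture(scope="session")
def if_recordings():
    """Factory for cached IF recordings keyed by (state, N, replicate)."""
    cache: dict = {}

    def get(state: str, n: int, rep: int = 0):
        key = (state, n, rep)
        if key not in cache:
            res = simulate(state, n, rep)
            raster = bin_events(res.events, BIN_WIDTH)
            cache[key] = (res, raster, compute_moments(raster))
        return cache[key]

    return get


@pytest.fixture(scope="session")
def if_fits(if_recordings):
    """Factory for cached K-pairwise fits keyed by (state, N, replicate)."""
    cache: dict = {}

    def get(state: str, n: int, rep: int = 0, fit_pk: bool = True):
        key = (state, n, rep, fit_pk)
        if key not in cache:
            _, _, data = if_recordings(state, n, rep)
            sched = scaled_schedule(n)
            cfg = SamplerConfig(n_samples=sched.mc_samples, n_chains=1,
                                seed=17 + rep)
            model, trace = bm_fit(data, sched, cfg, seed=23 + rep, fit_pk=fit_pk)
            cache[key] = (model, trace)
        return cache[key]

    return get
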