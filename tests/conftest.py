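"""Shared fixtures: small simulations in the three regimes the tests need."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tmtbridge as tb

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: Archetype shapes with both stage offsets nonzero and a margin from the
#: |log2FC| = 1 call threshold, so noiseless planted-set recovery is
#: well-posed (no knife-edge values, no stage with an exactly-zero change).
MARGIN_OFFSETS = {
    "down_steady": (0.0, -1.3, -2.2),
    "dip_recover": (0.0, -1.4, 0.6),
    "peak_early": (0.0, 1.5, 0.4),
    "gradual_up": (0.0, 0.8, 1.6),
    "early_jump": (0.0, 2.0, 2.0),
}

#: Shared per-archetype baselines making the myoblast-abundance component
#: informative, as it is for real co-regulated protein classes.
ARCHETYPE_BASES = {
    "down_steady": 13.0,
    "dip_recover": 14.0,
    "peak_early": 15.0,
    "gradual_up": 16.0,
    "early_jump": 12.0,
}


def noiseless_config(n_proteins=600, seed=3, **overrides):
    """Noise-free simulation with margin archetypes and planted treatment effects."""
    kwargs = dict(
        n_proteins=n_proteins,
        seed=seed,
        noise_sd_log2=0.0,
        fraction_per_archetype={k: 0.08 for k in MARGIN_OFFSETS},
        archetype_offsets=MARGIN_OFFSETS,
        multiplex_batch_log2=(0.0, 0.7, -0.4),
        effect_grid=(
            ("vehicle", "EM,LM", 1.5, 0.04),
            ("tmx", "M", -1.5, 0.03),
            ("tmx", "LM", -1.5, 0.02),
            ("tmx", "M,EM,LM", 1.5, 0.005),
        ),
    )
    kwargs.update(overrides)
    return tb.SimulationConfig(**kwargs)


def archetype_cluster_config(n_proteins=1000, seed=3, noise=0.0, **overrides):
    """Equal-fraction archetypes with shared per-archetype baselines."""
    kwargs = dict(
        n_proteins=n_proteins,
        seed=seed,
        noise_sd_log2=noise,
        fraction_per_archetype={k: 0.1 for k in ARCHETYPE_BASES},
        archetype_offsets=MARGIN_OFFSETS,
        base_log2_by_archetype=ARCHETYPE_BASES,
        effect_grid=(),
    )
    kwargs.update(overrides)
    return tb.SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def noiseless_run():
    cfg = noiseless_config()
    truth, matrices, design = tb.simulate(cfg)
    bridged = tb.normalize(matrices, design)
    return cfg, truth, matrices, design, bridged


@pytest.fixture(scope="session")
def noisy_run():
    cfg = tb.SimulationConfig(n_proteins=2000, seed=7)
    truth, matrices, design = tb.simulate(cfg)
    bridged = tb.normalize(matrices, design)
    return cfg, truth, matrices, design, bridged


def planted_nonflat(truth):
    return set(truth.index[truth["archetype"] != "flat"])


def bh_brute_force(p):
    """Step-up definition evaluated literally: adj at rank i is the minimum of
    m * p_(j) / j over all ranks j >= i, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    adj = np.empty(m)
    for i in range(m):
        tail = sorted_p[i:] * m / np.arange(i + 1, m + 1)
        adj[order[i]] = min(tail.min(), 1.0)
    return adj
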