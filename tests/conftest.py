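"""Shared synthetic-data fixtures.

Simulations are session-scoped: several test modules interrogate the
same planted architecture, and the generators are deterministic, so one
draw per scenario is enough.
"""

from __future__ import annotations

import numpy as np
import pytest

from loopforge import synthetic


def _spaced_loop_specs(n_bins, enrichment, every_dynamic=None, start=30, pad=18, seed_step=9):
    """Planted loops tiling a chromosome with varied anchor separations."""
    specs = []
    pos, k = start, 0
    while pos < n_bins - 80:
        sep = 15 + (k * seed_step) % 50
        cf = {"WT": 1.0, "MKO": 1.0}
        if every_dynamic and k % every_dynamic == every_dynamic - 1:
            cf = {"WT": 1.0, "MKO": 1.0 / 3.0}
        specs.append(
            synthetic.LoopSpec(
                anchor1=pos * 10_000,
                anchor2=(pos + sep) * 10_000,
                enrichment=enrichment,
                condition_factors=cf,
            )
        )
        pos += sep + pad
        k += 1
    return specs


@pytest.fixture(scope="session")
def recall_sim():
    """50 loops of enrichment 5 on a 30 Mb chromosome at 10 kb."""
    n_bins = 3000
    specs = _spaced_loop_specs(n_bins, enrichment=5.0)[:50]
    cfg = synthetic.SynthConfig(
        chrom_length=n_bins * 10_000, resolution=10_000, depth=12_000_000,
        loop_specs=specs, replicates_per_condition=1,
    )
    matrices, truth = synthetic.generate_hic_experiment(cfg, seed=11)
    return cfg, matrices, truth


@pytest.fixture(scope="session")
def differential_sim():
    """~33 loops, every fourth lost three-fold in the second condition, 2 reps."""
    n_bins = 2000
    specs = _spaced_loop_specs(n_bins, enrichment=6.0, every_dynamic=4)
    cfg = synthetic.SynthConfig(
        chrom_length=n_bins * 10_000, resolution=10_000, depth=12_000_000,
        loop_specs=specs, replicates_per_condition=2,
    )
    matrices, truth = synthetic.generate_hic_experiment(cfg, seed=7)
    return cfg, matrices, truth


@pytest.fixture(scope="session")
def compartment_sim():
    """Checkerboard plaid at 100 kb: 200 bins, 2 Mb blocks, 4 replicates."""
    cfg = synthetic.SynthConfig(
        chrom_length=20_000_000, resolution=100_000, depth=2_000_000,
        compartment_block_size=2_000_000, plaid_strength=1.8,
        replicates_per_condition=4,
    )
    matrices, truth = synthetic.generate_hic_experiment(cfg, seed=13)
    return cfg, matrices, truth


@pytest.fixture(scope="session")
def boundary_sim():
    """Two boundaries of depletion 0.3 and 0.7 on a 5 Mb chromosome."""
    cfg = synthetic.SynthConfig(
        chrom_length=5_000_000, resolution=10_000, depth=2_500_000,
        boundary_positions=[(1_500_000, 0.3), (3_500_000, 0.7)],
        replicates_per_condition=2,
    )
    matrices, truth = synthetic.generate_hic_experiment(cfg, seed=17)
    return cfg, matrices, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
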