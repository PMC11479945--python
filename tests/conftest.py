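"""Shared fixtures: one session-scoped synthetic dataset at study-default size,
plus a miniature configuration for fast per-module checks."""

from __future__ import annotations

from pathlib import Path

import pytest

from tetdormancy import SimConfig, simulate_dataset

#: master seed of the session dataset; every test that consumes the shared
#: dataset sees the same draws.
SESSION_SEED = 1


def small_sim_config(seed: int = 11) -> SimConfig:
    """A scaled-down dataset for unit tests (seconds, not minutes)."""
    return SimConfig(
        seed=seed,
        n_chrom=2,
        chrom_length=400_000,
        n_tet1_peaks=70,
        n_tet2_peaks=50,
        frac_cobound=0.5,
        n_planted_targets=20,
        n_enhancers=12,
        n_primed_enhancers=16,
        n_promoters=15,
        n_l1md=40,
        n_decoy_p300=5,
        n_tfe3_standalone=20,
        n_tfe3_on_targets=8,
        n_footprint_regions=30,
        n_genes=60,
    )


@pytest.fixture(scope="session")
def sim_dataset(tmp_path_factory) -> tuple[Path, object, SimConfig]:
    """Full-size synthetic dataset (default SimConfig) shared by the session."""
    outdir = tmp_path_factory.mktemp("simdata")
    cfg = SimConfig(seed=SESSION_SEED)
    truth = simulate_dataset(cfg, outdir)
    return outdir, truth, cfg


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory) -> tuple[Path, object, SimConfig]:
    """Miniature synthetic dataset for fast unit/integration checks."""
    outdir = tmp_path_factory.mktemp("simsmall")
    cfg = small_sim_config()
    truth = simulate_dataset(cfg, outdir)
    return outdir, truth, cfg
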