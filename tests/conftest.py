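"""Shared fixtures: one default-scale synthetic bundle and its analysis,
generated once per session, plus a small fast configuration for determinism
and CLI tests."""

from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from demethylome.config import RunConfig
from demethylome.pipeline import run_full_analysis
from demethylome.simulate import SyntheticConfig, generate


def small_synthetic_config(seed: int = 1) -> SyntheticConfig:
    """Desk-scale-but-tiny configuration for fast determinism/CLI tests."""
    return SyntheticConfig(
        seed=seed,
        n_chroms=1,
        chrom_length=2_500_000,
        n_genes=200,
        n_derepressed=15,
        n_up=12,
        n_down=15,
        n_common_enhancers=40,
        n_unique_a_enhancers=10,
        n_unique_b_extra=20,
        n_extra_h3k4me1=10,
        n_replicate_noise_peaks=5,
        n_nonpromoter_cgi=8,
        n_tsg_derepressed=5,
        n_tsg_up=2,
        n_tsg_extra=4,
    )


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    return generate(SyntheticConfig(), outdir)


@pytest.fixture(scope="session")
def analysis(bundle, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("analysis")
    cfg = RunConfig.for_bundle(bundle.outdir, outdir, seed=1)
    manifest = run_full_analysis(cfg)
    return cfg, manifest


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("small_bundle")
    return generate(small_synthetic_config(), outdir)
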