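"""Shared fixtures: small simulated datasets generated at test time."""

import warnings

import numpy as np
import pandas as pd
import pytest

import alsblood as ab

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_config() -> ab.SimulationConfig:
    """Quarter-scale-of-the-default config used by most integration tests."""
    return ab.SimulationConfig(
        c1_n_als=30, c1_n_ctl=50, c2_n_als=20, c2_n_ctl=18, c2_n_mim=10,
        n_genes_c1=600, n_genes_c2=600, n_shared=520,
        n_degs=20, n_sex_genes=8,
        ref_markers_per_type=30, ref_samples_per_type=6,
        n_loci=60, seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """(expr_c1, expr_c2, samples, genes, truth) with survival filled."""
    e1, e2, samples, genes, truth = ab.synthdata.generate_cohorts(small_config)
    combined = ab.pipeline._combined(e1, e2)
    samples, truth = ab.synthdata.generate_survival(
        samples, combined, small_config, truth)
    return e1, e2, samples, genes, truth


@pytest.fixture(scope="session")
def reference_with_truth():
    """Reference compendium with strong (4-fold) planted markers."""
    return ab.synthdata.generate_reference(
        n_genes=800, markers_per_type=40, marker_fc=4.0,
        samples_per_type=8, noise_sd=0.3, seed=5)


@pytest.fixture(scope="session")
def null_config() -> ab.SimulationConfig:
    """No planted effects of any kind: the global-null study conditions."""
    return ab.SimulationConfig(
        c1_n_als=30, c1_n_ctl=50, c2_n_als=20, c2_n_ctl=18, c2_n_mim=10,
        n_genes_c1=600, n_genes_c2=600, n_shared=520,
        n_degs=0, n_sex_genes=0, sex_effect=0.0,
        composition_multipliers={}, surv_log_hr=0.0,
        ref_markers_per_type=30, ref_samples_per_type=6,
        n_loci=60, seed=7,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
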