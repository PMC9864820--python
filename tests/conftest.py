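"""Shared fixtures: small noise-free simulations with known ground truth."""

import numpy as np
import pytest

from venomics import (
    GroundTruth,
    PlantedToxin,
    SampleMetadata,
    SimulationConfig,
    build_clade_panel,
    synthesize_run,
)


@pytest.fixture
def clean_config():
    """Noise-free, jitter-free simulation: deconvolution should be exact."""
    return SimulationConfig(
        seed=7,
        mz_jitter_sd=0.0,
        noise_peaks_per_spectrum=0.0,
        intensity_noise_sd=0.0,
    )


def make_truth(toxins, n_samples=1, config=None):
    """Ground truth with a hand-planted toxin list over a tiny manifest."""
    manifest = [
        SampleMetadata(f"S{i + 1}", genus="GenusA", species="genusa_sp1", locality=f"loc{i + 1}")
        for i in range(n_samples)
    ]
    truth = GroundTruth(toxins=list(toxins), sample_manifest=manifest)
    truth.validate(config)
    return truth


@pytest.fixture
def single_toxin_run(clean_config):
    """One planted 13,328 Da toxin (charges 9–11), noise-free run."""
    toxin = PlantedToxin(
        toxin_id="T1",
        neutral_mass=13328.0,
        rt_center=10.0,
        base_intensity=1e4,
        charge_states=(9, 10, 11),
        member_samples={"S1": 1.0},
    )
    truth = make_truth([toxin], config=clean_config)
    run = synthesize_run(truth, "S1", clean_config)
    return run, toxin


@pytest.fixture
def rng():
    return np.random.default_rng(20230113)
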