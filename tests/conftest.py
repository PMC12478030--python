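"""Shared fixtures: small simulated datasets and (session-scoped) trained
benchmark runs reused across test modules so training happens once."""

from __future__ import annotations

import numpy as np
import pytest

from atacdae import (CellLabels, PeakMatrix, SimConfig, denormalize,
                     mask_corrupt, normalize, simulate)
from atacdae.evaluation import meta_cell_distance, per_cell_mse
from atacdae.imputation import impute
from atacdae.model import ModelConfig
from atacdae.training import TrainConfig, fit

# The scaled-down benchmark: 5 populations x 100 cells x 5000 peaks, the
# size at which the zero-separation experiment is run on one CPU.
BENCH_SIM = dict(n_types=5, cells_per_type=100, n_peaks=5000, seed=11)
BENCH_CHANNELS = dict(bottom_channels=16, top_channels=32)
BENCH_EPOCHS = 30

# Smaller fixture for the multi-seed ablation comparisons.
ABLA_SIM = dict(n_types=5, cells_per_type=60, n_peaks=1280)
ABLA_CHANNELS = dict(bottom_channels=8, top_channels=16)
ABLA_EPOCHS = 25


def run_benchmark(rate: float, sim_kwargs: dict, channels: dict, epochs: int,
                  seed: int = 7, mask_seed: int = 101,
                  use_masking: bool = True, use_classifier: bool = True) -> dict:
    """One full masking-benchmark run: simulate, mask, train, impute.

    The network is trained on the simulated data with per-epoch masking at
    the benchmark rate (the denoising-autoencoder corruption); recovery and
    retention are scored on an independent fixed mask realization.
    """
    sim = simulate(SimConfig(**sim_kwargs))
    pm = PeakMatrix(X=sim.matrix)
    norm = normalize(pm)
    labels = CellLabels(assignments=sim.labels)
    record = mask_corrupt(norm, rate, seed=mask_seed)

    model_cfg = ModelConfig(input_length=pm.n_peaks, n_populations=sim.config.n_types,
                            train_mask_rate=rate, use_masking=use_masking,
                            use_classifier=use_classifier, seed=seed, **channels)
    train_cfg = TrainConfig(epochs=epochs, seed=seed)
    net, history = fit(norm, labels, model_cfg, train_cfg)
    result = impute(record.corrupted, net)

    corrupted_counts = denormalize(record.corrupted.values.toarray(),
                                   record.corrupted.peak_denominators)
    return {
        "sim": sim, "truth": pm, "norm": norm, "labels": labels,
        "record": record, "net": net, "history": history, "result": result,
        "mse_imputed": per_cell_mse(pm.X, result.imputed_counts),
        "mse_corrupted": per_cell_mse(pm.X, corrupted_counts),
        "meta_dist": meta_cell_distance(result.imputed_normalized,
                                        norm.values, sim.labels),
    }


@pytest.fixture(scope="session")
def default_sim():
    """The simulator at its default configuration (full benchmark size)."""
    return simulate(SimConfig())


@pytest.fixture(scope="session")
def small_sim():
    """Tiny multi-population dataset for fast unit tests."""
    return simulate(SimConfig(n_types=3, cells_per_type=20, n_peaks=400, seed=5))


@pytest.fixture(scope="session")
def bench40():
    return run_benchmark(0.4, BENCH_SIM, BENCH_CHANNELS, BENCH_EPOCHS)


@pytest.fixture(scope="session")
def bench60():
    return run_benchmark(0.6, BENCH_SIM, BENCH_CHANNELS, BENCH_EPOCHS)


@pytest.fixture(scope="session")
def small_bench():
    """One small benchmark run shared by imputation/stability tests."""
    return run_benchmark(0.4, dict(**ABLA_SIM, seed=0), ABLA_CHANNELS,
                         ABLA_EPOCHS, seed=0)


@pytest.fixture(scope="session")
def ablation_runs():
    """Full model vs no-masking and no-classifier variants, three seeds."""
    out = {"full": [], "wam": [], "wmc": []}
    for seed in (0, 1, 2):
        sim_kwargs = dict(**ABLA_SIM, seed=seed)
        out["full"].append(run_benchmark(0.4, sim_kwargs, ABLA_CHANNELS,
                                         ABLA_EPOCHS, seed=seed))
        out["wam"].append(run_benchmark(0.4, sim_kwargs, ABLA_CHANNELS,
                                        ABLA_EPOCHS, seed=seed,
                                        use_masking=False))
        out["wmc"].append(run_benchmark(0.4, sim_kwargs, ABLA_CHANNELS,
                                        ABLA_EPOCHS, seed=seed,
                                        use_classifier=False))
    return out
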