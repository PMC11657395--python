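"""Shared fixtures: tiny model configs and a seeded toy fixture directory."""

from __future__ import annotations

import numpy as np
import pytest

from seq2epi.model import ModelConfig, init_params


#: Smallest config that exercises every architectural piece (8 tokens).
MINI_CONFIG = ModelConfig(
    input_length=1024,
    bin_size=128,
    seq_channels=8,
    n_tf_padded=4,
    n_heads=2,
    n_layers=1,
    n_signals=3,
    conv_kernel=5,
)


@pytest.fixture(scope="session")
def mini_config() -> ModelConfig:
    return MINI_CONFIG


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def mini_params():
    return init_params(MINI_CONFIG, np.random.default_rng(7))


@pytest.fixture(scope="session")
def sim_small(tmp_path_factory):
    """A small simulated fixture directory (64-kb genome, 16 windows)."""
    from seq2epi.synthetic_data import SimConfig, simulate

    config = SimConfig(
        seed=11,
        genome_length=65_536,
        window_length=4_096,
        sites_per_regulator=12,
        n_effect_variants=8,
        n_neutral_variants=8,
        n_decoy_loops=5,
    )
    outdir = tmp_path_factory.mktemp("sim_small")
    result = simulate(config, outdir)
    return result


# ---------------------------------------------------------------------------
# The toy recovery study: 512-kb genome, 8 TFs, 6 contexts (2 held out),
# one model per seed without attention guidance (base) and one with (guided).
# Several recovery tests share these runs, so they are trained once.
# ---------------------------------------------------------------------------

TOY_SEEDS = (0, 1, 2, 3, 4)
TRAIN_CONTEXTS = [0, 1, 2, 3]
HELD_OUT_CONTEXTS = [4, 5]


def _toy_train_config(alpha: float, seed: int):
    from seq2epi.training import TrainConfig

    return TrainConfig(
        learning_rate=1e-3,
        batch_size=4,
        steps=1000,
        alpha=alpha,
        seed=seed,
        warmup_steps=50,
        cosine_decay=True,
    )


@pytest.fixture(scope="session")
def toy_experiments(tmp_path_factory):
    """One simulated study + two trained models per seed.

    Returns a list of dicts with keys: seed, bundle, clean (noise-free
    signals), ds_train / ds_all (with contact matrices), params_base
    (alpha=0) and params_guided (alpha=2).
    """
    from seq2epi.core_data import SignalTensor
    from seq2epi.model import TOY_CONFIG
    from seq2epi.pipeline import build_dataset, load_bundle
    from seq2epi.synthetic_data import SimConfig, simulate
    from seq2epi.training import train

    runs = []
    for seed in TOY_SEEDS:
        outdir = tmp_path_factory.mktemp(f"toy_seed{seed}")
        simulate(SimConfig(seed=seed), outdir)
        bundle = load_bundle(outdir)
        clean = SignalTensor.from_hdf5(outdir / "signals_clean.h5").values
        ds_train = build_dataset(
            bundle, TOY_CONFIG, context_indices=TRAIN_CONTEXTS,
            include_contacts=True,
        )
        ds_all = build_dataset(
            bundle, TOY_CONFIG, context_indices=list(range(6)),
            include_contacts=True,
        )
        params_base, _ = train(
            None, ds_train, TOY_CONFIG, _toy_train_config(0.0, seed)
        )
        params_guided, _ = train(
            None, ds_train, TOY_CONFIG, _toy_train_config(2.0, seed)
        )
        runs.append(
            {
                "seed": seed,
                "outdir": outdir,
                "bundle": bundle,
                "clean": clean,
                "ds_train": ds_train,
                "ds_all": ds_all,
                "params_base": params_base,
                "params_guided": params_guided,
            }
        )
    return runs
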