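import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for helpers.py

from gapfill import (GenomeSpec, ModelConfig, TrainingConfig, build_model,
                     generate_genome, make_training_set, train_model)


@pytest.fixture(scope="session")
def periodic_genome():
    """A strictly 21-periodic genome: next base is a deterministic function
    of any >=21-base context."""
    spec = GenomeSpec(length=3000, gc_content=0.5, repeat_motif_len=21,
                      repeat_fraction=1.0, rng_seed=3)
    return generate_genome(spec)


@pytest.fixture(scope="session")
def periodic_model(periodic_genome):
    """A small model trained to convergence on the 21-periodic genome
    (window 24 > period, so the task is deterministic and learnable)."""
    cfg = ModelConfig(window_len=24, conv_channels=8, lstm_hidden=16,
                      dropout_rate=0.1)
    examples = make_training_set([periodic_genome], 24, step=1, rng_seed=0)
    model = build_model(cfg, seed=0)
    tc = TrainingConfig(max_epochs=12, early_stop_patience=4, batch_size=64,
                        rng_seed=0)
    train_model(model, examples, tc)
    return model, examples


@pytest.fixture(scope="session")
def tiny_model():
    """A barely-trained midget model for plumbing tests (save/load, pipeline)."""
    spec = GenomeSpec(length=1200, gc_content=0.5, repeat_motif_len=7,
                      repeat_fraction=1.0, rng_seed=5)
    genome = generate_genome(spec)
    cfg = ModelConfig(window_len=8, conv_channels=4, lstm_hidden=6,
                      dropout_rate=0.0)
    examples = make_training_set([genome], 8, step=1, rng_seed=0)
    model = build_model(cfg, seed=0)
    tc = TrainingConfig(max_epochs=6, early_stop_patience=3, batch_size=64,
                        rng_seed=0)
    train_model(model, examples, tc)
    return model
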