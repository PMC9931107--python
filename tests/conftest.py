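import numpy as np
import pytest

from vocemo import (CorpusSpec, EmotionLabel, EmotionPreset, default_presets,
                    generate_corpus, kernel_from_accuracy, simulate_responses)


@pytest.fixture(scope="session")
def small_corpus():
    """4 emotions x 5 utterances, SNR 30 dB, fixed seed."""
    return generate_corpus(CorpusSpec(n_per_emotion=5, noise_snr=30.0, seed=123))


@pytest.fixture(scope="session")
def stimuli_60():
    """60 balanced stimuli (15 per emotion) for panel simulations."""
    return [
        (f"s{i:03d}_{e.value}", e)
        for i in range(15)
        for e in (EmotionLabel.JOY, EmotionLabel.NEUTRAL,
                  EmotionLabel.SADNESS, EmotionLabel.ANGER)
    ]


@pytest.fixture(scope="session")
def two_group_table(stimuli_60):
    """Responses from a sharp in-group panel and a diffuse out-group panel."""
    import pandas as pd

    k_in = kernel_from_accuracy((0.85, 0.85, 0.85, 0.85), group_label="in_group")
    k_out = kernel_from_accuracy((0.55, 0.55, 0.55, 0.55), group_label="out_group")
    return pd.concat([
        simulate_responses(stimuli_60, k_in, n_experts=10, seed=11),
        simulate_responses(stimuli_60, k_out, n_experts=10, seed=22),
    ], ignore_index=True)


@pytest.fixture
def flat_preset():
    """Constant-pitch preset for oracle-style tracker checks."""
    def make(f0=220.0, jitter=0.0, excursion=0.0, tilt=0.0, duration=800.0):
        return EmotionPreset(
            EmotionLabel.NEUTRAL, f0_mean=f0, f0_excursion=excursion,
            duration_mean_ms=duration, duration_sd_ms=0.0,
            energy_tilt_db=tilt, jitter_sd_hz=jitter,
        )
    return make
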