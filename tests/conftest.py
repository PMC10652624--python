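import numpy as np
import pytest

from fogkit import (
    ForestConfig,
    SyntheticConfig,
    extract_features,
    generate_recording,
    train,
)


@pytest.fixture(scope="session")
def short_config():
    """One minute of default-parameter gait (walking + FOG episodes)."""
    return SyntheticConfig(duration=60.0, seed=5)


@pytest.fixture(scope="session")
def short_recording(short_config):
    rec, truth = generate_recording(short_config)
    return rec, truth


@pytest.fixture(scope="session")
def walking_recording():
    """Pure walking, no FOG episodes, default noise."""
    rec, truth = generate_recording(
        SyntheticConfig(duration=60.0, fog_episode_rate=0.0, seed=2)
    )
    return rec, truth


@pytest.fixture(scope="session")
def small_cohort():
    """Three 2-minute synthetic subjects with window features."""
    out = {}
    for seed in (21, 22, 23):
        rec, _ = generate_recording(
            SyntheticConfig(duration=120.0, seed=seed)
        )
        out[rec.subject_id] = extract_features(rec, hop=32)
    return out


@pytest.fixture(scope="session")
def trained_model(small_cohort):
    """Forest trained on the pooled small cohort."""
    import fogkit

    parts = list(small_cohort.values())
    merged = fogkit.FeatureSet(
        times=np.concatenate([f.times for f in parts]),
        matrix=np.vstack([f.matrix for f in parts]),
        labels=np.concatenate([f.labels for f in parts]),
        subject_id="pooled",
        columns=parts[0].columns,
    )
    return train(merged, ForestConfig(seed=0))
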