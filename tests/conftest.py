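import numpy as np
import pytest

from songpath import (
    FeatureMatrix,
    SyllableSpec,
    featurize_waveform,
    synth_syllable,
    zscore_matrix,
)


@pytest.fixture(scope="session")
def tone():
    """0.1 s pure 1 kHz tone at 44.1 kHz."""
    spec = SyllableSpec(id="tone1k", duration_s=0.1, f0_start_hz=1000, f0_end_hz=1000)
    return synth_syllable(spec)


@pytest.fixture(scope="session")
def three_type_matrix():
    """Z-scored feature matrix of three clearly distinct syllable types.

    20 syllables per type with small parameter jitter; returns
    (matrix, true_labels).
    """
    types = [
        dict(f0_start_hz=700, f0_end_hz=900, n_harmonics=3),
        dict(f0_start_hz=2600, f0_end_hz=2600, n_harmonics=1),
        dict(f0_start_hz=5200, f0_end_hz=3800, n_harmonics=1, noise_fraction=0.3),
    ]
    X, ids, labels = [], [], []
    for ti, params in enumerate(types):
        for j in range(20):
            jitter = dict(params)
            jitter["f0_start_hz"] += 12 * j
            jitter["f0_end_hz"] += 12 * j
            spec = SyllableSpec(
                id=f"type{ti}_{j}", duration_s=0.08, rng_seed=100 * ti + j, **jitter
            )
            X.append(featurize_waveform(synth_syllable(spec)))
            ids.append(spec.id)
            labels.append(ti)
    m = zscore_matrix(FeatureMatrix(X=np.array(X), ids=ids))
    return m, np.array(labels)
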