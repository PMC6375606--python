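import numpy as np
import pytest

import aortafinder as af


@pytest.fixture(scope="session")
def clean_phantom():
    """One artefact-free cine phantom with its ground truth."""
    return af.generate_phantom(af.PhantomConfig(seed=1))


@pytest.fixture(scope="session")
def processed(clean_phantom):
    """Stage I-III output (candidates + features) for the clean phantom."""
    series, _gt = clean_phantom
    return af.process_scan(series)


@pytest.fixture(scope="session")
def labelled(clean_phantom, processed):
    _series, gt = clean_phantom
    labels = af.label_candidates(
        processed.candidates, gt, processed.shape, processed.pixel_spacing_mm
    )
    return labels


@pytest.fixture(scope="session")
def separable_training_set():
    """Synthetic 3-class feature set with one informative dimension."""
    rng = np.random.default_rng(42)
    n_per = 80
    X = np.vstack(
        [
            np.hstack([rng.normal(mu, 0.3, (n_per, 1)), rng.normal(0, 1, (n_per, 4))])
            for mu in (0.0, 3.0, 6.0)
        ]
    )
    y = np.repeat([1, 2, 3], n_per)
    return X, y
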