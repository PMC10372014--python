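import numpy as np
import pytest

from serialign.masking import make_tissue_mask
from serialign.preprocessing import process_brightfield
from serialign.synthetic import SyntheticParams, generate_series


@pytest.fixture(scope="session")
def small_series():
    """A 4-image, 420-px series with mild deformation, shared across tests."""
    params = SyntheticParams(n_images=4, size=420, deformation_amplitude_px=4,
                             n_nuclei=120)
    return generate_series(params, seed=11)


@pytest.fixture(scope="session")
def small_processed(small_series):
    """Processed images + masks for the shared series."""
    masks = [make_tissue_mask(img) for img in small_series.images]
    processed = [process_brightfield(img) for img in small_series.images]
    for p, m in zip(processed, masks):
        p.mask = m.mask
    return processed, masks


@pytest.fixture(scope="session")
def small_features(small_processed):
    from serialign.features import detect_and_describe

    processed, masks = small_processed
    return [detect_and_describe(p.pixels, m.mask)
            for p, m in zip(processed, masks)]


@pytest.fixture(scope="session")
def small_matches(small_features):
    from serialign.features import match_all_pairs

    return match_all_pairs(small_features, seed=0)
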