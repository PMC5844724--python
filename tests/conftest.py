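import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from larctex import CohortSpec, StudyConfig, extract_cohort, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20259)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced phantom cohort (16 patients) with its feature table."""
    cspec = CohortSpec(
        n_responders_trg=8, n_nonresponders_trg=8, n_pcr=4, seed=11
    )
    images, labels = generate_cohort(cspec)
    cohort = extract_cohort(images, labels, StudyConfig(seed=11))
    return {"cspec": cspec, "images": images, "labels": labels, "cohort": cohort}


def random_masked_image(rng, size=24, density=0.4):
    """A random image with a random (nonempty) mask."""
    from larctex import MaskedImage

    pixels = rng.normal(200, 50, (size, size))
    mask = rng.random((size, size)) < density
    if not mask.any():
        mask[size // 2, size // 2] = True
    return MaskedImage(pixels=pixels, mask=mask, patient_id="T", rater="A")
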