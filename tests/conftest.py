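import numpy as np
import pytest

from cvquant import RenderParams, generate_vessel_tree, render_angiogram
from cvquant.preprocess import enhance_chain


@pytest.fixture(scope="session")
def tree20():
    """A medium-density ground-truthed tree shared across modules."""
    return generate_vessel_tree(20.0, seed=42)


@pytest.fixture(scope="session")
def speckled_angiogram(tree20):
    """The shared tree rendered at moderate speckle (shape 20)."""
    return render_angiogram(tree20, RenderParams(speckle_shape=20.0), seed=43)


@pytest.fixture(scope="session")
def enhanced_pair(speckled_angiogram):
    """(denoised intensity, phase response) for the shared angiogram."""
    den, _th, phase = enhance_chain(speckled_angiogram)
    return den, phase


def random_binary_map(rng: np.random.Generator, shape=(128, 128), p=0.2) -> np.ndarray:
    return (rng.random(shape) < p).astype(np.uint8)
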