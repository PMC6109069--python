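import numpy as np
import pytest

from protonpocket.pka import PocketFrame
from protonpocket.states import parse_label


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def two_residue_frame():
    """Hand-built toy geometry: one glutamate, one deprotonated aspartate,
    one K+ and a small burial shell; every term of the stand-in estimator
    is computable by hand from these coordinates."""
    oxygens = {
        "E343": np.array([[0.0, 0.0, 0.0], [0.12, 0.0, 0.0]]),  # centroid (0.06, 0, 0)
        "D824": np.array([[1.0, 0.0, 0.0], [1.12, 0.0, 0.0]]),  # centroid (1.06, 0, 0)
    }
    ions = {"K1": np.array([0.56, 0.0, 0.0])}  # 0.5 nm from the E343 centroid
    shell = np.array([[0.06, 0.3, 0.0]] * 15)  # 15 heavy atoms within r_burial of E343
    return PocketFrame(
        time_ns=0.0, oxygens=oxygens, ions=ions, k791=None,
        heavy_atoms=shell, state=parse_label("D824+"),
    )


@pytest.fixture
def planted_series():
    """A 250-frame synthetic pKa trajectory with the E795/E820 pair planted
    at rho = -0.923 in a state where only E795 is protonated."""
    from protonpocket.synth import PkaEnsembleSpec, gen_pka_series

    state = parse_label("E795+D824+D942+")
    spec = PkaEnsembleSpec(seed=11, planted_pairs={("E795", "E820"): -0.923})
    return gen_pka_series(state, 0, spec)
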