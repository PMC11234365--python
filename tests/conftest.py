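import numpy as np
import pytest

from nmfit.fixtures import make_benchmark_case, make_two_domain_toy
from nmfit.model_io import Structure


def make_structure(coords, names=None, resids=None, masses=None, ss=None,
                   elements=None, chains=None):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return Structure(
        names=np.array(names if names is not None else ["CA"] * n),
        elements=np.array(elements if elements is not None else ["C"] * n),
        res_names=np.array(["ALA"] * n),
        res_ids=np.array(resids if resids is not None else range(1, n + 1)),
        chain_ids=np.array(chains if chains is not None else ["A"] * n),
        coords=coords,
        masses=np.array(masses if masses is not None else [12.0] * n),
        ss=np.array(ss) if ss is not None else None,
    )


@pytest.fixture(scope="session")
def helix():
    """20-residue Cα pseudo-helix annotated as helical."""
    t = np.arange(20)
    coords = np.stack([2.3 * np.cos(1.75 * t), 2.3 * np.sin(1.75 * t),
                       1.5 * t], axis=1)
    return make_structure(coords, ss=["H"] * 20)


@pytest.fixture(scope="session")
def toy_pair():
    """Default two-domain hinge toy (open, closed, frame Cα RMSD)."""
    return make_two_domain_toy(seed=0)


@pytest.fixture(scope="session")
def benchmark(toy_pair):
    """(start, target map, target structure) fitting benchmark at 5 Å."""
    s_open, s_closed, _ = toy_pair
    return make_benchmark_case((s_open, s_closed), resolution=5.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
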