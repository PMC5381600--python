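import numpy as np
import pytest

from basecomp.extraction import load_bundle
from basecomp.simulate import make_toy_genome


@pytest.fixture(scope="session")
def toy_bundle(tmp_path_factory):
    """A seeded toy genome bundle plus its truth record and loaded form."""
    out = tmp_path_factory.mktemp("toy")
    res = make_toy_genome(out, n_genes=12, n_samples=6, seed=3)
    bundle = load_bundle(res["genomes"], res["annotation"], res["samples"])
    return {"paths": res, "bundle": bundle, "truth": res["truth"]}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_nh_model(seed: int):
    """A random branch-nonstationary GTR model for oracle tests."""
    from basecomp.ancestry import BRANCHES, NonStationaryGtrModel
    r = np.random.default_rng(seed)
    def simplex():
        v = r.dirichlet(np.ones(4) * 5.0)
        return np.maximum(v, 1e-3) / np.maximum(v, 1e-3).sum()
    model = NonStationaryGtrModel(root_freqs=simplex())
    for b in BRANCHES:
        e = np.exp(r.normal(scale=0.5, size=6))
        model.exch[b] = e / e[-1]
        model.freqs[b] = simplex()
        model.lengths[b] = float(r.uniform(0.05, 0.5))
    return model
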