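import numpy as np
import pytest

import boronfit as bf


@pytest.fixture(scope="session")
def builtin():
    return bf.builtin_boronate_params()


@pytest.fixture(scope="session")
def fullset():
    """Built-in boronate library merged with the shipped fallback subset."""
    return bf.fixture_params()


@pytest.fixture(scope="session")
def ma():
    """Methylamino fixture (topology, conformer, four tau definitions)."""
    return bf.toy_boronate_fixture("methylamino")


@pytest.fixture(scope="session")
def ma_scan(ma):
    """36-frame 10° scan of the O1-B-C7-N torsion of the methylamino
    fixture."""
    return bf.scan_torsion(ma.topology, ma.conformer, ma.torsions[1], step=10.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20230322)


def random_geometry(rng, n=4, spread=2.0, min_sep=0.5):
    """Random non-degenerate atom positions for internal-coordinate tests."""
    while True:
        coords = rng.uniform(-spread, spread, size=(n, 3))
        ok = True
        for i in range(n - 1):
            if np.linalg.norm(coords[i + 1] - coords[i]) < min_sep:
                ok = False
        if ok:
            return coords
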