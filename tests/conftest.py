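import numpy as np
import pytest

from hemifc.atlas import Roi, RoiAtlas, default_atlas


def make_paired_atlas(n_pairs: int, n_midline: int = 0) -> RoiAtlas:
    """k homotopic pairs (L_r0/R_r0, ...) plus optional midline ROIs."""
    rois = []
    for i in range(n_pairs):
        rois.append(Roi(f"L_r{i}", f"region {i} left", "L", f"R_r{i}"))
        rois.append(Roi(f"R_r{i}", f"region {i} right", "R", f"L_r{i}"))
    for i in range(n_midline):
        rois.append(Roi(f"M_m{i}", f"midline {i}", "M", None))
    return RoiAtlas(tuple(rois))


@pytest.fixture(scope="session")
def atlas105():
    return default_atlas()


@pytest.fixture
def atlas4():
    return make_paired_atlas(4)


@pytest.fixture
def atlas5m():
    return make_paired_atlas(5, n_midline=2)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_correlation(n: int, rng: np.random.Generator) -> np.ndarray:
    """A random valid correlation matrix (Wishart-style)."""
    a = rng.standard_normal((n, n + 3))
    c = a @ a.T
    d = np.sqrt(np.diag(c))
    r = c / np.outer(d, d)
    np.fill_diagonal(r, 1.0)
    return r
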