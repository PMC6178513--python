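import numpy as np
import pytest

import mammocad as mc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom():
    """A default two-mass phantom with its ground-truth masks."""
    spec = mc.PhantomSpec(seed=3)
    img, masks, pect = mc.make_phantom(spec)
    return img, masks, pect


@pytest.fixture(scope="session")
def pectoral_phantom():
    spec = mc.PhantomSpec(seed=3, with_pectoral=True)
    return mc.make_phantom(spec)


def naive_sparse_lbp(band, tol):
    """Independent per-pixel reference for the sparse uniform-LBP histogram."""
    from mammocad.sparselbp import _BIN_OF, _RING

    h, w = band.shape
    hist = np.zeros(58)
    kept = 0
    n_fg = 0
    for r in range(1, h - 1):
        for c in range(1, w - 1):
            win = band[r - 1:r + 2, c - 1:c + 2]
            if (np.abs(win) > tol).sum() > 2:
                n_fg += 1
                code = 0
                for p, (dr, dc) in enumerate(_RING):
                    if band[r + dr, c + dc] >= band[r, c]:
                        code |= 1 << p
                b = _BIN_OF[code]
                if b >= 0:
                    hist[b] += 1
                    kept += 1
    if kept:
        hist /= kept
    return hist, n_fg
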