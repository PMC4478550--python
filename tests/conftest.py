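import numpy as np
import pytest

from ensloc import features as F
from ensloc import phantom as P


@pytest.fixture(scope="session")
def registry():
    return F.default_registry()


@pytest.fixture(scope="session")
def small_field():
    """One mixed phantom field with artifacts, shared across read-only tests."""
    spec = P.PhantomSpec(
        n_cells=60,
        class_mix={"cytoplasm": 0.5, "cell periphery": 0.5},
        dead_fraction=0.05,
        ghost_fraction=0.05,
        seed=7,
    )
    rfp, gfp, truth = P.generate_micrograph(spec)
    return spec, rfp, gfp, truth


@pytest.fixture(scope="session")
def cyto_crop_vectors(registry):
    """Feature vectors of 40 cytoplasm crops (shared, read-only)."""
    rng = np.random.default_rng(5)
    out = []
    for _ in range(40):
        crop = P.render_crop("cytoplasm", rng)
        fv = F.extract_from_crop(crop, registry)
        if fv.extractable:
            out.append(fv)
    return out


@pytest.fixture(scope="session")
def periphery_crop_vectors(registry):
    rng = np.random.default_rng(6)
    out = []
    for _ in range(40):
        crop = P.render_crop("cell periphery", rng)
        fv = F.extract_from_crop(crop, registry)
        if fv.extractable:
            out.append(fv)
    return out
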