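import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from phenoroof import CameraGeometry

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture
def geometry():
    """Device-default geometry: B=7.5 cm, f=880 px, C=204.5 cm, r=17 cm."""
    return CameraGeometry()


@pytest.fixture
def geometry_f400():
    """Small-focal geometry used by the hand-computable examples."""
    return CameraGeometry(focal_px=400.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# independent brute-force oracles (used by unit and acceptance tests)


def otsu_oracle(gray: np.ndarray) -> int:
    """Exhaustive 256-threshold between-class-variance argmax.

    Classes are (<= t, > t); ties break to the smallest t.
    """
    counts = np.bincount(np.asarray(gray, dtype=np.uint8).ravel(),
                         minlength=256).astype(float)
    n = counts.sum()
    levels = np.arange(256, dtype=float)
    best, best_t = -np.inf, None
    for t in range(255):
        w0 = counts[: t + 1].sum()
        w1 = n - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = (levels[: t + 1] * counts[: t + 1]).sum() / w0
        m1 = (levels[t + 1:] * counts[t + 1:]).sum() / w1
        v = w0 * w1 * (m0 - m1) ** 2
        if v > best:
            best, best_t = v, t
    return best_t


def dilate_oracle(mask: np.ndarray) -> np.ndarray:
    """3x3 Minkowski dilation by neighborhood enumeration; outside = False."""
    m = np.asarray(mask, dtype=bool)
    h, w = m.shape
    out = np.zeros_like(m)
    for i in range(h):
        for j in range(w):
            out[i, j] = m[max(0, i - 1): i + 2, max(0, j - 1): j + 2].any()
    return out


def erode_oracle(mask: np.ndarray) -> np.ndarray:
    """3x3 Minkowski erosion by neighborhood enumeration; outside = False."""
    m = np.pad(np.asarray(mask, dtype=bool), 1, constant_values=False)
    h, w = mask.shape
    out = np.zeros(mask.shape, dtype=bool)
    for i in range(h):
        for j in range(w):
            out[i, j] = m[i: i + 3, j: j + 3].all()
    return out


def clean_mask_oracle(mask: np.ndarray) -> np.ndarray:
    """Closing (dilation then erosion) then erosion, all by enumeration."""
    return erode_oracle(erode_oracle(dilate_oracle(mask)))


@pytest.fixture
def oracles():
    class O:
        otsu = staticmethod(otsu_oracle)
        dilate = staticmethod(dilate_oracle)
        erode = staticmethod(erode_oracle)
        clean = staticmethod(clean_mask_oracle)
    return O
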