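import numpy as np
import pytest

import eegfuse as ef

BANDS_DBG = ("delta", "beta", "gamma")


@pytest.fixture(scope="session")
def default_spec() -> ef.SyntheticSpec:
    """Generator defaults: 2 subjects x 4 recordings/class, 30 s at 128 Hz."""
    return ef.SyntheticSpec(seed=1)


@pytest.fixture(scope="session")
def default_recordings(default_spec):
    recordings, _ = ef.generate_dataset(default_spec)
    return recordings


@pytest.fixture(scope="session")
def c1_tensor(default_recordings) -> ef.BandTensor:
    """Default dataset preprocessed with the C1 temporal combination."""
    return ef.preprocess_dataset(default_recordings, combo="C1")


@pytest.fixture(scope="session")
def dbg_tensor(c1_tensor) -> ef.BandTensor:
    """delta/beta/gamma slice of the preprocessed default dataset."""
    return c1_tensor.select_bands(BANDS_DBG)


def make_tiny_tensor(
    n: int = 90,
    t: int = 128,
    c: int = 4,
    bands: tuple[str, ...] = ("beta", "gamma"),
    separation: float = 1.0,
    seed: int = 0,
) -> ef.BandTensor:
    """Small in-memory BandTensor with a class-conditional mean shift.

    ``separation = 0`` gives label-free noise. ``n`` must be divisible by 3;
    classes are exactly balanced.
    """
    assert n % 3 == 0
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(3), n // 3)
    order = rng.permutation(n)
    labels = labels[order]
    data = {}
    for b in bands:
        x = rng.standard_normal((n, t, c)).astype(np.float32)
        x += (separation * (labels[:, None, None] - 1)).astype(np.float32)
        data[b] = x
    return ef.BandTensor(
        data=data,
        labels=labels,
        subjects=np.array(["S00"] * n, dtype=object),
        channels=tuple(f"CH{i}" for i in range(c)),
        fs=128.0,
        window_s=t / 128.0,
        step_s=t / 128.0,
        manifest=__import__("pandas").DataFrame(),
    )
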