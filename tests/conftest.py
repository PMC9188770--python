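import numpy as np
import pytest

from sargamap import DEFAULT_PALETTE, Label, LabelMask, SceneSpec, make_scene


@pytest.fixture
def palette():
    return dict(DEFAULT_PALETTE)


@pytest.fixture
def small_scene():
    """A deterministic 64x64 jittered scene pair."""
    return make_scene(
        SceneSpec(
            height=64,
            width=64,
            sargassum_fraction=0.3,
            sand_fraction=0.3,
            seed=7,
        )
    )


@pytest.fixture
def random_mask_pair():
    """Factory for random 3-class mask pairs of a given size."""

    def _make(seed: int, size: int = 32) -> tuple[LabelMask, LabelMask]:
        rng = np.random.default_rng(seed)
        t = rng.integers(0, 3, size=(size, size)).astype(np.uint8)
        p = rng.integers(0, 3, size=(size, size)).astype(np.uint8)
        return LabelMask(t), LabelMask(p)

    return _make


def make_mask(labels) -> LabelMask:
    return LabelMask(np.asarray(labels, dtype=np.uint8))


@pytest.fixture
def mask_from_counts():
    """Build a 1-row mask with the given per-class pixel counts."""

    def _make(n_sarg: int, n_sand: int, n_other: int) -> LabelMask:
        row = (
            [int(Label.SARGASSUM)] * n_sarg
            + [int(Label.SAND)] * n_sand
            + [int(Label.OTHER)] * n_other
        )
        return LabelMask(np.asarray([row], dtype=np.uint8))

    return _make
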