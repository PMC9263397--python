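import numpy as np
import pytest

from gfcpipe import Bold4D, CohortConfig, EffectRegion, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_bold(rng):
    """Tiny 4x4x4 x 60 BOLD image, TR = 2 s."""
    data = rng.normal(size=(4, 4, 4, 60))
    return Bold4D(data, np.eye(4), tr=2.0)


@pytest.fixture(scope="session")
def effect_bundle():
    """15/1/15 cohort with a +0.4 connectivity effect planted for group S1."""
    cfg = CohortConfig(
        n_per_group=(15, 1, 15),
        grid_shape=(12, 12, 12),
        n_volumes=100,
        effect_regions=(EffectRegion(1, "S1", 0.4),),
        seed=5,
    )
    return generate_cohort(cfg)


def random_gfc_stack(rng, n_subjects, mask_shape=(6, 6, 6), n_mask=40):
    """Random GFC-like maps over a random mask; returns (maps, mask3d)."""
    from gfcpipe import GFCMap

    mask3d = np.zeros(mask_shape, dtype=bool)
    flat = rng.choice(np.prod(mask_shape), size=n_mask, replace=False)
    mask3d.flat[flat] = True
    maps = []
    for i in range(n_subjects):
        vol = np.full(mask_shape, np.nan)
        vol[mask3d] = rng.normal(size=n_mask)
        maps.append(GFCMap(vol, np.eye(4), f"sub-{i:03d}"))
    return maps, mask3d
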