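import numpy as np
import pytest

from restmvpa import (Bold4D, CohortSpec, EffectSpec, MaskVolume, SeedSpec,
                      generate_cohort)

AFFINE_3MM = np.diag([3.0, 3.0, 3.0, 1.0])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_mask():
    return MaskVolume(data=np.ones((8, 8, 8), bool), affine=AFFINE_3MM)


@pytest.fixture
def random_bold(rng, small_mask):
    data = rng.standard_normal((8, 8, 8, 60))
    return Bold4D(data=data, affine=AFFINE_3MM, tr_s=3.0, subject_id="sub-x")


def _coherence_effect(center=(8, 8, 8), radius=2.0, a0=0.0, a1=3.0):
    return EffectSpec(
        kind="coherence",
        region=SeedSpec(name="planted", center_vox=center, radius_vox=radius),
        group_amplitudes=(a0, a1),
    )


@pytest.fixture(scope="session")
def null_cohort(tmp_path_factory):
    """10+10 pure-AR(1) cohort, 16^3 x 80, no planted effects."""
    out = tmp_path_factory.mktemp("null_cohort")
    spec = CohortSpec(n_per_group=(10, 10), dims=(16, 16, 16), n_volumes=80,
                      rng_seed=2024)
    manifest = generate_cohort(spec, out)
    return {"dir": out, "manifest": manifest, "spec": spec}


@pytest.fixture(scope="session")
def effect_cohort(tmp_path_factory):
    """8+8 cohort with one strong coherence sphere (amplitude 3x noise sd)."""
    out = tmp_path_factory.mktemp("effect_cohort")
    spec = CohortSpec(n_per_group=(8, 8), dims=(16, 16, 16), n_volumes=80,
                      effects=[_coherence_effect()], rng_seed=777)
    manifest = generate_cohort(spec, out)
    return {"dir": out, "manifest": manifest, "spec": spec}


def make_coherence_effect(**kw):
    return _coherence_effect(**kw)
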