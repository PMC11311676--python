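import numpy as np
import pytest

from prostacad import MRIVolume, PhantomSpec, generate_case, generate_cohort


def tiny_spec(grid=(48, 48, 12), **kw):
    """A reduced-grid phantom spec that keeps all geometric invariants."""
    defaults = dict(
        grid_shape=grid,
        spacing_mm=(0.75, 0.75, 3.0),
        gland_radius_mm=14.0,
        lesion_radius_mm_range=(3.0, 6.0),
    )
    defaults.update(kw)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def small_spec():
    return tiny_spec(grid=(64, 64, 16), gland_radius_mm=18.0,
                     lesion_radius_mm_range=(4.0, 7.0))


@pytest.fixture(scope="session")
def small_malignant_case(small_spec):
    return generate_case(small_spec, label=1, seed=11)


@pytest.fixture(scope="session")
def small_benign_case(small_spec):
    return generate_case(small_spec, label=0, seed=12)


@pytest.fixture(scope="session")
def tiny_cohort():
    """12 cases on a small grid, both classes present."""
    spec = tiny_spec(class_ratio=(1, 1), lesion_count_range=(1, 2))
    cases, manifest = generate_cohort(spec, 12, seed=5)
    return cases, manifest


def random_volume(shape, seed=0, spacing=(1.0, 1.0, 1.0), modality="T2W"):
    rng = np.random.default_rng(seed)
    return MRIVolume(data=rng.standard_normal(shape), spacing_mm=spacing,
                     modality=modality)
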