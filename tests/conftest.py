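import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import redoxim as rx
from redoxim.pipeline import RunConfig, analyze_records

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def noise_free_field():
    """One TNBC-like FOV with zero noise and no per-cell scatter."""
    spec = rx.preset_spec("tnbc_like", read_noise_sd=0.0, intensity_cv=0.0)
    return rx.generate_field(spec, "d1", "d1_f1", seed=11)


@pytest.fixture(scope="session")
def study_bundle():
    """The default two-group study at realistic noise, one fixed seed."""
    return rx.generate_study(seed=1)


@pytest.fixture(scope="session")
def study_records(study_bundle):
    return analyze_records(study_bundle.fields, study_bundle.annotations, RunConfig())


def make_annotation(cell_mask, nucleus_mask, **kw):
    defaults = dict(
        cell_id="c0", field_id="f0", dish_id="d0",
        cell_line="L", receptor_group="triple_negative", mitotic=False,
    )
    defaults.update(kw)
    return rx.CellAnnotation(cell_mask=cell_mask, nucleus_mask=nucleus_mask, **defaults)


def square_mask(shape, r0, c0, r1, c1):
    m = np.zeros(shape, dtype=bool)
    m[r0:r1, c0:c1] = True
    return m
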