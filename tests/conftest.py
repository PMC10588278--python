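import numpy as np
import pytest
from hypothesis import settings

from epidstitch.fluence import FluenceMap
from epidstitch.synthetic import SyntheticScenario, generate_scenario

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")


def make_map(pixels, row_sp=1.0, col_sp=1.0, plane=1000.0,
             kind="calculated", iso=0, label="f"):
    return FluenceMap(
        pixels=np.asarray(pixels, dtype=float),
        row_spacing_mm=row_sp, col_spacing_mm=col_sp,
        plane_distance_mm=plane, source_kind=kind,
        isocenter_index=iso, field_label=label,
    )


def small_scenario(**overrides) -> SyntheticScenario:
    """A compact two-isocenter phantom: 12 cm fields, 6 cm overlap,
    1.4 mm imager-plane grid — small enough for fast gamma analysis while
    keeping the junction geometry in the clinical overlap regime."""
    params = dict(
        n_isocenters=2, field_height_cm=12.0, field_width_cm=8.0,
        couch_shifts_cm=(6.0,), spacing_mm=1.4, seed=1,
    )
    params.update(overrides)
    return SyntheticScenario(**params)


@pytest.fixture
def two_iso_data():
    return generate_scenario(small_scenario())


@pytest.fixture
def noiseless_data():
    return generate_scenario(
        small_scenario(noise_sd_fraction=0.0, modulation=False)
    )
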