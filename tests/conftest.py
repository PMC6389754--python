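import numpy as np
import pytest

import alphashift as ash


@pytest.fixture(scope="session")
def layout():
    return ash.standard_1020_layout()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def noiseless_10hz_segment():
    """Narrowband 10 Hz oscillator, posterior topography, no background."""
    return ash.generate_segment(
        ash.OscillatorSpec(10.0, bandwidth=0.05, amplitude=2.0,
                           anterior_spread=0.2),
        ash.NoiseSpec(white_sd=0.0), seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced 12/10/12 cohort shared by the slower statistical tests."""
    design = ash.default_design(seed=11)
    import dataclasses
    design = dataclasses.replace(design,
                                 n_per_group={"HS": 12, "GSC": 10,
                                              "PSC": 12})
    return ash.generate_cohort(design)


def global_shifts(segments):
    out = []
    for seg in segments:
        ps = ash.power_spectrum(ash.rereference_common_average(seg))
        out.append(ash.alpha_shift(ps).global_log2_shift)
    return np.array(out)
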