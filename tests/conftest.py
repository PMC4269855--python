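import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from multicna.io import MarkerMap, SignalMatrix
from multicna.synthetic import CNVRegion, CohortSpec, simulate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_markers():
    return MarkerMap(
        np.array(["m1", "m2", "m3", "m4", "m5", "m6"]),
        np.array(["1", "1", "1", "2", "2", "X"]),
        np.array([100, 200, 500, 150, 300, 50]),
    )


@pytest.fixture
def toy_signal(toy_markers, rng):
    values = rng.normal(2.0, 0.1, size=(6, 2)).clip(min=0)
    return SignalMatrix(toy_markers, ["S01", "S02"], values, "copy_number")


@pytest.fixture(scope="session")
def small_cohort():
    """Two-chromosome cohort with one loss, one gain and a causal marker."""
    spec = CohortSpec(
        name="unit-small",
        n_patients=12,
        markers_per_chrom={"1": 120, "2": 80},
        regions=(
            CNVRegion("1", 30, 40, 1, 1.0),
            CNVRegion("2", 20, 30, 3, 0.5),
        ),
        cn_noise_sd=0.2,
        causal_markers=(140,),
        causal_effects=(1.0,),
        response_noise_sd=0.3,
        seed=77,
    )
    return simulate_cohort(spec)
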