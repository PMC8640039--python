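import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from sbmie import FeatureTable, SampleMetadata, SimulationSpec, simulate


@pytest.fixture
def small_table() -> tuple[FeatureTable, SampleMetadata]:
    """Tiny two-group content table with a deterministic layout."""
    rng = np.random.default_rng(11)
    samples = [f"FM.content.{i}" for i in range(4)] + [
        f"SBM40.content.{i}" for i in range(4)
    ]
    data = pd.DataFrame(
        rng.lognormal(10, 0.3, size=(6, 8)),
        index=[f"f{j}" for j in range(6)],
        columns=samples,
    )
    meta = pd.DataFrame(
        {
            "sample_id": samples,
            "group": ["FM"] * 4 + ["SBM40"] * 4,
            "compartment": ["content"] * 8,
            "ion_mode": ["positive"] * 8,
        }
    ).set_index("sample_id")
    return FeatureTable(data), SampleMetadata(meta)


@pytest.fixture(scope="session")
def planted_simulation():
    """Mid-sized cohort with planted differential, diet-derived and exchanged
    features, shared by the recovery tests."""
    spec = SimulationSpec(
        n_features={"positive": 200},
        frac_differential=0.05,
        frac_diet_derived=0.05,
        frac_exchanged=0.05,
        seed=3,
    )
    return spec, simulate(spec)
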