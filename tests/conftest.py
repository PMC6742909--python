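import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from bmprev import RegistryDataset

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_registry(
    n: int,
    source_name: str = "fixture",
    coverage: float | None = None,
    **columns,
) -> RegistryDataset:
    """Build a registry dataset from column overrides (scalars broadcast)."""
    data = {"person_id": [f"R{i:05d}" for i in range(n)]}
    defaults = {
        "sex": "female",
        "age_years": 45,
        "region": "Midlands",
        "disease_type": "RRMS",
        "dmt_status": "current-12mo",
        "dmt_type": "oral",
        "disease_duration_years": 8.0,
    }
    defaults.update(columns)
    for name, value in defaults.items():
        if np.ndim(value) == 0:
            data[name] = [value] * n
        else:
            assert len(value) == n
            data[name] = list(value)
    return RegistryDataset(df=pd.DataFrame(data), source_name=source_name, coverage=coverage)


@pytest.fixture
def registry_factory():
    return make_registry
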