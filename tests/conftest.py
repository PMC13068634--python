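import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def regular_polygon(n: int, radius: float = 1.0, center=(0.0, 0.0)) -> np.ndarray:
    t = np.linspace(0, 2 * math.pi, n, endpoint=False)
    return np.column_stack([center[0] + radius * np.cos(t), center[1] + radius * np.sin(t)])


@pytest.fixture(scope="session")
def circle_polygon() -> np.ndarray:
    return regular_polygon(360)


@pytest.fixture(scope="session")
def unit_square() -> np.ndarray:
    return np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


@pytest.fixture(scope="session")
def control_population():
    from senmorph.synthetic import generate_control_population

    return generate_control_population(n=1000, seed=42)


@pytest.fixture(scope="session")
def control_model(control_population):
    from senmorph.gating import fit_gating_model

    return fit_gating_model(control_population.frame)


@pytest.fixture(scope="session")
def cell_control_population():
    from senmorph.synthetic import generate_control_population

    return generate_control_population(n=500, seed=123, compartment="cell")


def synthetic_records_frame(area, irregularity, compartment="nucleus", condition="control"):
    """Bare measurement table for gating tests that need exact marginals."""
    area = np.asarray(area, dtype=float)
    irregularity = np.asarray(irregularity, dtype=float)
    return pd.DataFrame({
        "object_id": [f"r{i}" for i in range(len(area))],
        "condition": condition,
        "timepoint": 0.0,
        "compartment": compartment,
        "area": area,
        "irregularity": irregularity,
    })
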