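import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from codeharmony.store import CovariateTable, EventTable
from codeharmony.synth import generate_cohort, scenario_substitution

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def events_csv(tmp_path):
    """Factory writing a small events CSV and returning its path."""

    def write(rows, header="patient_id,date,code,code_type", name="events.csv"):
        path = tmp_path / name
        path.write_text("\n".join([header, *rows]) + "\n")
        return path

    return write


@pytest.fixture
def toy_events():
    """Hand-built event table: two patients, three codes."""
    frame = pd.DataFrame(
        {
            "patient_id": ["p1", "p1", "p1", "p2", "p2"],
            "date": pd.to_datetime(
                ["2020-01-01", "2020-01-05", "2020-02-01", "2020-01-01", "2020-01-02"]
            ),
            "code": ["A", "B", "A", "A", "C"],
            "code_type": ["ICD10"] * 5,
        }
    )
    return EventTable(site_id="A", frame=frame)


@pytest.fixture
def toy_covars():
    frame = pd.DataFrame(
        {
            "person_time": [2.0, 0.5],
            "age": [60.0, 70.0],
            "sex": [1.0, 0.0],
            "insulin_use": [0.0, 1.0],
            "elixhauser": [3.0, 5.0],
        },
        index=pd.Index(["p1", "p2"], name="patient_id"),
    )
    return CovariateTable(frame=frame)


@pytest.fixture(scope="session")
def substitution_cohort():
    """One modest paired cohort reused by several tests."""
    config = scenario_substitution(n_patients=300, seed=42)
    ev_a, cov_a, ev_b, cov_b, truth = generate_cohort(config)
    return config, ev_a, cov_a, ev_b, cov_b, truth


def pooled_design(cov_a, cov_b):
    Z = np.vstack([cov_a.design_matrix(True), cov_b.design_matrix(True)])
    site = np.r_[np.ones(len(cov_a.frame)), np.zeros(len(cov_b.frame))]
    pt = np.r_[cov_a.person_time.to_numpy(), cov_b.person_time.to_numpy()]
    return Z, site, pt
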