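import pandas as pd
import pytest

from cathdose.synthetic import CohortConfig, generate_cohort, generate_summaries


@pytest.fixture(scope="session")
def small_cohort():
    """200-procedure synthetic cohort (summaries + ground truth), seeded."""
    return generate_summaries(CohortConfig(n_procedures=200, seed=11))


@pytest.fixture(scope="session")
def event_cohort():
    """60-procedure cohort with the full per-event stream, seeded."""
    return generate_cohort(CohortConfig(n_procedures=60, seed=7))


@pytest.fixture()
def worked_example_row():
    """The single-procedure case used throughout the docs: a 10-year-old
    35 kg boy with a cumulative biplane DAP of 683.13 cGy·cm²."""
    return {
        "procedure_id": "example",
        "patient_id": "pt-example",
        "age": 10.0,
        "sex": "male",
        "height": 140.0,
        "weight_kg": 35.0,
        "procedure_type": "Diagnostic",
        "total_dap": 683.13,
        "dap_frontal": 480.0,
        "dap_lateral": 203.13,
        "dap_fluoro": 600.0,
        "dap_cine": 83.13,
        "total_kerma_irp": 60.0,
        "fluoro_time": 600.0,
        "cine_frames": 150,
        "is_biplane": True,
    }


@pytest.fixture()
def worked_example_frame(worked_example_row):
    return pd.DataFrame([worked_example_row])
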