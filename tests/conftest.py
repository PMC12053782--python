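import pandas as pd
import pytest

import dreamwake as dw


@pytest.fixture(scope="session")
def table1():
    """The packaged 69-study review table (context factors only)."""
    return dw.load_table1()


@pytest.fixture
def write_awakenings(tmp_path):
    """Write a toy awakening-record CSV and return its path."""

    def _write(rows, name="awakenings.csv"):
        path = tmp_path / name
        pd.DataFrame(rows).to_csv(path, index=False)
        return path

    return _write


def awakening_row(
    study_id="S01",
    subject_id="p1",
    health="healthy",
    stage="N2",
    report="with_recall",
    age=25,
    sex="f",
):
    return {
        "study_id": study_id,
        "subject_id": subject_id,
        "health": health,
        "stage": stage,
        "report": report,
        "age": age,
        "sex": sex,
    }
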