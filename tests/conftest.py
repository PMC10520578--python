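import pandas as pd
import pytest

from msmediate import SimParams, generate_panel
from msmediate.preprocess import build_analysis_table, derive_analysis_variables


@pytest.fixture(scope="session")
def small_params():
    return SimParams(n_individuals=400, seed=7)


@pytest.fixture(scope="session")
def small_panel(small_params):
    return generate_panel(small_params)


@pytest.fixture(scope="session")
def analysis_table(small_panel):
    return build_analysis_table(derive_analysis_variables(small_panel))


@pytest.fixture(scope="session")
def mid_table():
    """Moderately sized analysis table for weighting/estimation checks."""
    params = SimParams(n_individuals=4000, seed=21)
    return build_analysis_table(derive_analysis_variables(generate_panel(params)))


@pytest.fixture()
def three_person_panel():
    """Hand-built panel: person 1 has waves 1-3, person 2 a single wave,
    person 3 waves 1-2 with a gap to wave 4."""
    rows = []
    spec = {
        1: [1, 2, 3],
        2: [1],
        3: [1, 2, 4],
    }
    for pid, waves in spec.items():
        for w in waves:
            rows.append(
                dict(
                    pid=pid,
                    wave=w,
                    age=30 + w,
                    female=pid % 2,
                    nonwhite=0,
                    educ="high",
                    region="r01",
                    tenure=0,
                    benefits=0,
                    couple=1,
                    n_children=pid - 1,
                    pcs=50.0 + pid + w,
                    mcs=48.0 - w,
                    employed=(pid + w) % 2,
                    income=1000.0 + 100 * pid + 10 * w,
                    ghq=(pid + w) % 6,
                )
            )
    df = pd.DataFrame(rows)
    df["educ"] = pd.Categorical(df["educ"], categories=["high", "med", "low"])
    df["region"] = pd.Categorical(df["region"], categories=[f"r{i+1:02d}" for i in range(12)])
    return df
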