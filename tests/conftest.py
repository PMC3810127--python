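import numpy as np
import pandas as pd
import pytest

from rppahet import (EffectModel, StudyDesign, VarianceModel, generate_study)


@pytest.fixture(scope="session")
def default_design():
    return StudyDesign.default()


@pytest.fixture
def small_design():
    return StudyDesign(
        n_patients=3,
        samples_per_patient=(4, 3, 3),
        n_healthy_tubes=3,
        n_contralateral_tubes=1,
        n_proteins=5,
        phospho_flags=(True, False, True, False, False),
    )


@pytest.fixture
def small_study(small_design):
    variance = VarianceModel(1000.0, 0.2, 0.25, 0.27,
                             n_proteins=small_design.n_proteins)
    return generate_study(small_design, variance, EffectModel.null(), seed=11)


def make_meta(records):
    """Build a metadata frame from (sample_id, patient_id, tissue_class) tuples."""
    return pd.DataFrame(records, columns=["sample_id", "patient_id", "tissue_class"]) \
        .assign(side="na")


@pytest.fixture
def toy_matrix_meta():
    """One patient with tumor samples {1,2,3}, one unrelated normal sample."""
    matrix = pd.DataFrame(
        {"t1": [1.0], "t2": [2.0], "t3": [3.0], "n1": [2.0]},
        index=pd.Index(["A"], name="protein"))
    meta = make_meta([("t1", "p1", "tumor"), ("t2", "p1", "tumor"),
                      ("t3", "p1", "tumor"), ("n1", "n1", "healthy_tube")])
    return matrix, meta
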