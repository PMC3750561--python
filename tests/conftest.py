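import numpy as np
import pandas as pd
import pytest

from pathscape import ExpressionCohort, GeneSet, GeneSetCollection


@pytest.fixture
def tiny_gmt(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text(
        "S1\tfirst set\tTP53\tEGFR\tMYC\n"
        "S2\tsecond set\tBRCA1\tBRCA2\tATM\tCHEK2\n"
        "S3\tthird set\tTP53\tBRCA1\tKRAS\n"
    )
    return path


@pytest.fixture
def small_collection():
    return GeneSetCollection(sets=[
        GeneSet(name="A", genes=frozenset({"G1", "G2", "G3"})),
        GeneSet(name="B", genes=frozenset({"G3", "G4", "G5", "G6"})),
    ])


def make_cohort(values: np.ndarray, genes=None, samples=None, patients=None,
                cancer="CAN") -> ExpressionCohort:
    n_genes, n_samples = values.shape
    genes = genes or [f"G{i+1}" for i in range(n_genes)]
    samples = samples or [f"S{j+1}" for j in range(n_samples)]
    patients = patients or [f"P{j+1}" for j in range(n_samples)]
    meta = pd.DataFrame(
        {"patient_id": patients, "cancer_label": cancer,
         "survival_days": np.nan, "event": np.nan, "prior_subtype": np.nan},
        index=pd.Index(samples, name="sample_id"),
    )
    return ExpressionCohort(pd.DataFrame(values, index=genes, columns=samples), meta)


@pytest.fixture
def cohort_3x2():
    return make_cohort(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]))
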