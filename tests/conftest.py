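import numpy as np
import pandas as pd
import pytest

from txresponse.expression import AnnotatedCounts, NormalizedMatrix


def make_annotation(sample_specs):
    """sample_specs: list of (sample_id, patient_id, therapy, timepoint, response, batch)."""
    return pd.DataFrame(
        sample_specs,
        columns=["sample_id", "patient_id", "therapy", "timepoint", "response", "batch"],
    ).set_index("sample_id")


@pytest.fixture
def small_cohort():
    """4 patients (2 ICI, 2 MAPKi), PT+OT each, hand-set counts for 5 genes."""
    rng = np.random.default_rng(42)
    specs = []
    for therapy in ("ICI", "MAPKi"):
        for k, response in enumerate(("R", "NR")):
            patient = f"{therapy}_p{k}"
            for tp in ("PT", "OT"):
                specs.append((f"{patient}_{tp}", patient, therapy, tp, response, "b1"))
    ann = make_annotation(specs)
    counts = pd.DataFrame(
        rng.integers(10, 1000, size=(5, len(ann))),
        index=[f"g{i}" for i in range(5)],
        columns=ann.index,
    )
    return AnnotatedCounts(counts=counts, annotation=ann)


def plain_matrix(values, genes=None, samples=None):
    """Wrap a 2-D array as a NormalizedMatrix with unit factors."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=genes, columns=samples)
    ones = pd.Series(1.0, index=df.columns)
    return NormalizedMatrix(values=df, tmm_factors=ones,
                            effective_lib_sizes=ones * 1e6)
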