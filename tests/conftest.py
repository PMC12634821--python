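import numpy as np
import pandas as pd
import pytest

import pepmatch as pm

CONDITIONS = ("Ctx", "Ctrl")


@pytest.fixture
def config():
    return pm.RunConfig(maldi_csv="maldi.csv", lcms_csv="lcms.csv")


def make_maldi(rows, conditions=CONDITIONS):
    """Build an in-memory MaldiPeakTable from (mz, treated, control) tuples."""
    df = pd.DataFrame(rows, columns=["mz", *conditions])
    df.insert(0, "peak_id", np.arange(len(df)))
    df = df.sort_values("mz", kind="stable").reset_index(drop=True)
    return pm.MaldiPeakTable(df=df, conditions=conditions)


def make_lcms(rows, conditions=CONDITIONS):
    """Build an LcmsPeptideTable from (accession, sequence, mh, treated, control)."""
    df = pd.DataFrame(
        rows, columns=["accession", "sequence", "theoretical_mh", *conditions]
    )
    df["description"] = ""
    df["gene"] = ""
    df["modification_annotation"] = ""
    cols = ["accession", "description", "gene", "sequence",
            "modification_annotation", "theoretical_mh", *conditions]
    return pm.LcmsPeptideTable(df=df[cols], conditions=conditions)


@pytest.fixture(scope="session")
def default_instance():
    """One seeded default synthetic instance, shared across tests."""
    params = pm.SyntheticParams(seed=1)
    maldi, lcms, truth = pm.generate_dataset(params)
    return params, maldi, lcms, truth


@pytest.fixture(scope="session")
def default_run(default_instance):
    """Pipeline result on the default synthetic instance."""
    _, maldi, lcms, truth = default_instance
    cfg = pm.RunConfig(maldi_csv="synthetic", lcms_csv="synthetic")
    result = pm.run_pipeline(cfg, maldi=maldi, lcms=lcms, write_output=False)
    return result, truth
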