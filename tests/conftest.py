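import numpy as np
import pandas as pd
import pytest

import dnmkit as dk


@pytest.fixture(scope="session")
def gene_model():
    """A mid-sized synthetic per-gene mutational model."""
    return dk.make_gene_model(2000, seed=1)


@pytest.fixture(scope="session")
def tiny_model():
    """Four genes with hand-set rates, for enumeration oracles."""
    return pd.DataFrame(
        {
            "gene": ["A", "B", "C", "D"],
            "cds_length": [1000, 2000, 1500, 3000],
            "mu_syn": [1e-5, 2e-5, 1e-5, 3e-5],
            "mu_mis": [2e-5, 1e-5, 4e-5, 2e-5],
            "mu_lof": [1e-6, 5e-6, 2e-6, 1e-6],
            "frac_cpg": 0.2,
            "pli": [0.95, 0.5, 0.99, 0.1],
            "set_memberships": ["risk", "", "dd", ""],
        }
    )


def make_records(rows):
    """Build a mutation-record table from (proband, gene, consequence, cadd) rows."""
    df = pd.DataFrame(rows, columns=["proband_id", "gene", "consequence", "cadd"])
    df["group"] = "case"
    df["variant_type"] = np.where(
        df["consequence"].isin(["frameshift", "inframe_indel"]), "indel", "snv"
    )
    df["at_interface"] = False
    df["af_gnomad_nonneuro"] = 0.0
    df["af_tommo"] = 0.0
    return df


@pytest.fixture
def simple_records():
    return make_records(
        [
            ("p1", "A", "nonsense", 38.0),
            ("p1", "A", "synonymous", 2.0),
            ("p2", "B", "missense", 22.0),
            ("p2", "C", "missense", 15.0),
            ("p3", "D", "synonymous", 1.0),
        ]
    )
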