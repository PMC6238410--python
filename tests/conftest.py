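import numpy as np
import pandas as pd
import pytest

import prodisc as p


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def planted_cohort():
    """Two-histotype cohort with one planted KRAS effect shared between
    BRCA and STAD (5 proteins, 3x noise, frequency 0.5)."""
    cfg = p.SimConfig(
        n_histotypes=3,
        cases_per_histotype=60,
        n_proteins=40,
        n_genes=25,
        driver_specs=(
            p.DriverSpec(
                "KRAS", ("BRCA", "STAD"), 0.5,
                {0: 3.0, 1: 3.0, 2: -3.0, 3: 3.0, 4: -3.0},
            ),
        ),
        seed=11,
    )
    return cfg, p.generate(cfg)


def make_matrix(values, case_ids=None, protein_ids=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    case_ids = case_ids or [f"c{i}" for i in range(values.shape[0])]
    protein_ids = protein_ids or [f"p{i}" for i in range(values.shape[1])]
    return p.ProteinMatrix(pd.DataFrame(values, index=case_ids, columns=protein_ids))


def make_annotations(histotypes, case_ids=None, batches=None):
    case_ids = case_ids or [f"c{i}" for i in range(len(histotypes))]
    table = pd.DataFrame({"histotype": histotypes}, index=case_ids)
    if batches is not None:
        table["batch_id"] = batches
    return p.Annotations(table)


def make_mutations(records, case_ids=None):
    rec = pd.DataFrame(
        records,
        columns=["case_id", "gene_symbol", "variant_classification", "protein_change"],
    )
    return p.MutationProfile(rec, case_ids=list(case_ids) if case_ids else [])
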