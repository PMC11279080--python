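import numpy as np
import pandas as pd
import pytest

import poolcomm as pc
from poolcomm import tables


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic survey (seed 1), shared across tests."""
    cfg = pc.ScenarioConfig(seed=1)
    frame, chem, t16, t18, taxonomy, truth = pc.generate_bundle(cfg)
    return {
        "config": cfg,
        "frame": frame,
        "chem": chem,
        "t16": t16,
        "t18": t18,
        "taxonomy": taxonomy,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def rarefied_16s(default_bundle):
    t16 = default_bundle["t16"]
    return tables.rarefy(t16, int(t16.totals().min()), seed=7)


@pytest.fixture()
def tiny_table():
    """Hand-entered 3-sample x 4-taxon count table."""
    data = pd.DataFrame(
        [[10, 0, 3, 1], [0, 5, 2, 1], [4, 4, 4, 0]],
        index=["s1", "s2", "s3"],
        columns=["t1", "t2", "t3", "t4"],
    )
    return tables.CountTable(data)


@pytest.fixture()
def tiny_taxonomy():
    df = pd.DataFrame(
        {
            "domain": ["Eukaryota", "Eukaryota", "Bacteria", "Eukaryota"],
            "phylum": ["Streptophyta", "Alveolata", "Proteobacteria", "unassigned"],
            "class": ["c"] * 4,
            "order": ["o"] * 4,
            "family": ["f"] * 4,
            "genus": ["g1", "g2", "g3", "g4"],
        },
        index=["t1", "t2", "t3", "t4"],
    )
    return tables.TaxonomyTable(df)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
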