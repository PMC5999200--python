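import numpy as np
import pytest

from gsikit.genotype_io import BaselineCollection, table_from_records
from gsikit.synthetic_data import SimConfig, generate_baseline


@pytest.fixture
def toy_baseline() -> BaselineCollection:
    """Two collections x two loci, six fish; alleles overlap partially."""
    table = table_from_records(
        {
            "a1": [("120", "120"), ("100", "103")],
            "a2": [("120", "123"), ("100", "100")],
            "a3": [("120", "120"), ("103", "103")],
            "b1": [("123", "123"), ("106", "106")],
            "b2": [("123", "126"), ("103", "106")],
            "b3": [("126", "126"), ("106", "106")],
        },
        loci=["L1", "L2"],
        labels=["A", "A", "A", "B", "B", "B"],
    )
    return BaselineCollection(table, ["A", "B"], {"A": "A", "B": "B"})


@pytest.fixture
def disjoint_baseline() -> BaselineCollection:
    """Two collections fixed for entirely disjoint alleles at 4 loci."""
    loci = [f"L{k}" for k in range(4)]
    recs = {}
    labels = []
    for i in range(10):
        recs[f"a{i}"] = [("100", "100")] * 4
        labels.append("A")
    for i in range(10):
        recs[f"b{i}"] = [("200", "200")] * 4
        labels.append("B")
    table = table_from_records(recs, loci=loci, labels=labels)
    return BaselineCollection(table, ["A", "B"], {"A": "A", "B": "B"})


@pytest.fixture(scope="session")
def synth_small():
    """Moderately separated 6-population synthetic baseline (session-wide)."""
    return generate_baseline(
        SimConfig(
            n_pops=6,
            n_loci=24,
            mean_alleles_per_locus=6.0,
            fst_target=0.05,
            n_per_pop=30,
            missing_rate=0.02,
            error_rate=0.0,
            n_duplicates=0,
            seed=101,
        )
    )
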