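import numpy as np
import pandas as pd
import pytest

import eelmorph as em


@pytest.fixture
def valid_record():
    return em.SpecimenRecord(
        taxon_id="ext_001",
        status="extant",
        clade="Congroidei",
        L_axis1=312.4,
        L_axis2=18.7,
        head_length=31.2,
        L_head_in_vertebrae=6.3,
        N_PCV=52,
        N_CV=88,
        AR_head=2.41,
        AR_PCV=1.22,
        AR_CV=1.31,
    )


@pytest.fixture
def small_dated_tree():
    """(((A,B),C),D) dated: root 10, (A,B,C) 6, (A,B) 3, extant tips."""
    phy = em.from_newick("(((A,B),C),D);")
    ages = {"A": 0.0, "B": 0.0, "C": 0.0, "D": 0.0}
    for leaf in phy.tree.leaf_node_iter():
        leaf.age = ages[leaf.taxon.label]
    phy.mrca(["A", "B"]).age = 3.0
    phy.mrca(["A", "B", "C"]).age = 6.0
    phy.root.age = 10.0
    return phy


def random_records(rng: np.random.Generator, n: int):
    """Valid SpecimenRecords with all eight shape-index inputs present."""
    out = []
    for i in range(n):
        L1 = float(rng.uniform(100, 1500))
        out.append(
            em.SpecimenRecord(
                taxon_id=f"r{i}",
                status="extant",
                clade="synthetic",
                L_axis1=L1,
                L_axis2=L1 / float(rng.uniform(5, 40)),
                head_length=0.1 * L1,
                L_head_in_vertebrae=float(rng.uniform(2, 12)),
                N_PCV=int(rng.integers(10, 120)),
                N_CV=int(rng.integers(10, 200)),
                AR_head=float(rng.uniform(0.5, 4)),
                AR_PCV=float(rng.uniform(0.4, 3)),
                AR_CV=float(rng.uniform(0.4, 3)),
            )
        )
    return out
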