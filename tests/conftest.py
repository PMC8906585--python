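import itertools

import numpy as np
import pytest

from causalpath import CausalKG, NodeKind, worked_fixture


@pytest.fixture
def g1():
    """Five-node documentation KG: D-|P1, P1->P2, P2-|P3, P3->X, D->P2."""
    kg, _, _ = worked_fixture()
    return kg


@pytest.fixture
def g1_signatures():
    _, drug_sig, disease_sig = worked_fixture()
    return drug_sig, disease_sig


def random_typed_kg(rng: np.random.Generator, max_nodes: int = 10) -> CausalKG:
    """A small random KG honoring the edge-type constraints, with occasional
    parallel contradictory edges."""
    n_chem = int(rng.integers(1, 3))
    n_dis = int(rng.integers(1, 3))
    n_prot = int(rng.integers(2, max(3, max_nodes - n_chem - n_dis + 1)))
    kg = CausalKG()
    chems = [f"c{i}" for i in range(n_chem)]
    prots = [f"p{i}" for i in range(n_prot)]
    diss = [f"x{i}" for i in range(n_dis)]
    for c in chems:
        kg.add_node(c, NodeKind.CHEMICAL)
    for p in prots:
        kg.add_node(p, NodeKind.PROTEIN)
    for d in diss:
        kg.add_node(d, NodeKind.DISEASE)
    for src, tgt in itertools.chain(
        itertools.product(chems, prots),
        itertools.product(prots, prots),
        itertools.product(prots, diss),
    ):
        if src == tgt:
            continue
        if rng.random() < 0.3:
            kg.add_edge(src, tgt, 1 if rng.random() < 0.5 else -1)
            if rng.random() < 0.1:  # parallel contradictory edge
                kg.add_edge(src, tgt, -1)
                kg.add_edge(src, tgt, 1)
    return kg
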