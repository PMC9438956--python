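import numpy as np
import pytest

from gipredict import simulate as sim
from gipredict.features import AnnotationTable, GeneAnnotation
from gipredict.graph import PPINetwork


@pytest.fixture()
def toy_net() -> PPINetwork:
    """Path a-b-c, triangle d-e-f, bridge c-d, isolated gene z."""
    return PPINetwork.from_edges(
        [("a", "b"), ("b", "c"), ("d", "e"), ("e", "f"), ("d", "f"),
         ("c", "d")],
        extra_nodes=["z"],
    )


@pytest.fixture()
def vocab5() -> list[str]:
    return [f"T{i}" for i in range(5)]


@pytest.fixture()
def toy_table(vocab5) -> AnnotationTable:
    table = AnnotationTable(vocab5)
    bits = {
        "a": [1, 0, 1, 0, 0], "b": [1, 1, 0, 0, 0], "c": [0, 0, 0, 0, 1],
        "d": [0, 1, 1, 0, 0], "e": [0, 0, 0, 0, 0], "f": [1, 1, 1, 1, 1],
        "z": [0, 0, 0, 1, 0],
    }
    fitness = {"a": "L", "b": "R", "c": "N", "d": "L", "e": "N",
               "f": "R", "z": "N"}
    pident = {"a": 0.0, "b": 35.2, "c": 80.0, "d": 12.5, "e": 0.0,
              "f": 99.9, "z": 50.0}
    for g in bits:
        table.add(GeneAnnotation(g, np.array(bits[g], dtype=float),
                                 pident[g], fitness[g]))
    return table


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study shared by slower integration tests."""
    net = sim.generate_network(150, 3, seed=7)
    table = sim.generate_annotations(sim.gene_ids(150), n_terms=12, seed=8)
    truth = sim.recovery_ground_truth(n_terms=12)
    singles = sim.generate_single_labels(table, net, truth.s_mn, seed=9)
    return {"net": net, "table": table, "truth": truth, "singles": singles}
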