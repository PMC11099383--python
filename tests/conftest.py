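import numpy as np
import pandas as pd
import pytest

from gpcraxes.network import AxisNetwork, Edge, Enzyme, Ligand, Receptor


@pytest.fixture
def tiny_network() -> AxisNetwork:
    """3 receptors, 2 ligands, 2 enzymes, 5 valid edges."""
    receptors = {
        r.id: r
        for r in [
            Receptor("R1", "ClassA", frozenset({"Gi/o"})),
            Receptor("R2", "ClassA", frozenset({"Gq/11"})),
            Receptor("R3", "ClassB", frozenset(), orphan=True),
        ]
    }
    ligands = {
        l.id: l
        for l in [
            Ligand("L1", "ligand one", "peptide"),
            Ligand("L2", "ligand two", "metabolite", {"chebi": "123"}),
        ]
    }
    enzymes = {
        e.id: e
        for e in [
            Enzyme("E1", frozenset({"plasma membrane"}), frozenset({"acyltransferase"}), 10),
            Enzyme("E2", frozenset({"extracellular"}), frozenset({"hydrolase"}), 5),
        ]
    }
    edges = [
        Edge("L1", "R1", "ligand_receptor", action="agonist"),
        Edge("L2", "R2", "ligand_receptor", action="antagonist"),
        Edge("E1", "L2", "enzyme_ligand", direction="LR"),
        Edge("E2", "L1", "enzyme_ligand", direction="UN"),
        Edge("R2", "E1", "receptor_enzyme", confidence=300),
    ]
    return AxisNetwork(receptors=receptors, ligands=ligands, enzymes=enzymes, edges=edges)


@pytest.fixture
def de_tables() -> dict[str, pd.DataFrame]:
    """Four hand-built subtype DE tables over six genes."""

    def table(rows):
        return pd.DataFrame(rows, columns=["gene", "lfc", "pvalue", "padj"])

    genes = ["R1", "R2", "R3", "L1", "L2", "E1"]

    def rows(lfcs, padjs):
        return [(g, l, p, p) for g, l, p in zip(genes, lfcs, padjs)]

    return {
        "S1": table(rows([2.0, -1.5, 0.2, 1.5, -1.2, 2.5], [0.001] * 6)),
        "S2": table(rows([1.8, -1.4, 0.1, 1.2, -1.1, 2.0], [0.001, 0.001, 0.5, 0.05, 0.001, 0.001])),
        "S3": table(rows([0.1, 0.2, 0.0, 0.3, -0.1, 0.2], [0.5] * 6)),
        "S4": table(rows([0.0, 0.1, 0.1, -0.2, 0.2, -0.1], [0.9] * 6)),
    }


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
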