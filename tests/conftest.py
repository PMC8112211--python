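"""Shared fixtures: tiny hand-built panels, signatures and graphs."""

import numpy as np
import pandas as pd
import pytest

from combiscreen.signatures import PerturbationPanel, SignedSignature


def make_signature(directions: dict, name: str = "sig", support: int = 1) -> SignedSignature:
    """Signature from {gene: direction}; magnitude mirrors the direction."""
    genes = list(directions)
    d = np.array([directions[g] for g in genes], dtype=int)
    return SignedSignature.from_arrays(
        genes, d, d.astype(float), np.where(d != 0, support, 0), name=name
    )


def make_panel(records: list[tuple], genes: list[str]) -> PerturbationPanel:
    """Panel from [(compound, cell_line, experiment, scores-list), ...]."""
    index = pd.MultiIndex.from_tuples(
        [(c, cl, e) for c, cl, e, _ in records],
        names=["compound", "cell_line", "experiment"],
    )
    mat = np.array([scores for _, _, _, scores in records], dtype=float)
    return PerturbationPanel(pd.DataFrame(mat, index=index, columns=genes))


@pytest.fixture
def path_graph4():
    import networkx as nx

    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("c", "d")])
    return g


@pytest.fixture
def tiny_cohort():
    """8-gene cohort with two strong planted genes (one up, one down)."""
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(8)]
    base = np.full((8, 12), 100.0)
    base[0, :6] *= 8.0  # up in cases
    base[1, :6] /= 8.0  # down in cases
    values = pd.DataFrame(
        rng.poisson(base), index=genes, columns=[f"s{i}" for i in range(12)]
    )
    conditions = pd.Series(["case"] * 6 + ["control"] * 6, index=values.columns)
    from combiscreen.signatures import ExpressionCohort

    return ExpressionCohort(values, conditions)
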