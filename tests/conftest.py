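import itertools

import numpy as np
import pandas as pd
import pytest

from ernakit.fixtures import make_annotation, preset
from ernakit.enhancers import combine_markers
from ernakit.networks import EDGE_COLUMNS, Network


@pytest.fixture(scope="session")
def tiny_ann():
    """Tiny planted genome (seed 1): 5 PCGs, 3 planted eRNAs, 4 decoys."""
    return make_annotation(preset("tiny", seed=1))


@pytest.fixture(scope="session")
def tiny_enhancers(tiny_ann):
    return combine_markers(tiny_ann.markers, mode="overlap", min_support=2, flank=3000)


def edge_rows(pairs, kind="coexpr"):
    """Build an edge table from (source, target) pairs."""
    return pd.DataFrame(
        [
            {
                "source": s,
                "target": t,
                "kind": kind,
                "rho": np.nan,
                "p": np.nan,
                "q": np.nan,
                "evidence": "",
            }
            for s, t in pairs
        ],
        columns=EDGE_COLUMNS,
    )


def network_from_pairs(pairs, roles=None, kind="coexpr"):
    nodes = {}
    for s, t in pairs:
        nodes.setdefault(s, "pcg")
        nodes.setdefault(t, "pcg")
    if roles:
        nodes.update(roles)
    return Network(nodes, edge_rows(pairs, kind=kind))


def two_bridged_cliques():
    """Two 4-cliques {a1..a4}, {b1..b4} joined by the single edge a1-b1."""
    pairs = []
    for g in ("a", "b"):
        pairs += [
            (f"{g}{x}", f"{g}{y}") for x, y in itertools.combinations(range(1, 5), 2)
        ]
    pairs.append(("a1", "b1"))
    return network_from_pairs(pairs)


def random_network(rng, n_nodes=15, p=0.25, prefix="n"):
    nodes = [f"{prefix}{i}" for i in range(n_nodes)]
    pairs = [
        (a, b)
        for a, b in itertools.combinations(nodes, 2)
        if rng.random() < p
    ]
    return network_from_pairs(pairs, roles={n: "pcg" for n in nodes})
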