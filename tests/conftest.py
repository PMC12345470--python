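import datetime

import numpy as np
import pandas as pd
import pytest

from keystonenet import BipartiteNetwork, Lineage, OtuTable, SampleMeta


def make_otu_table(marker, rows, samples):
    """rows: list of (otu_id, lineage string, counts list)."""
    counts = pd.DataFrame(
        {oid: c for oid, _, c in rows}, index=samples, dtype="int64"
    ).T
    counts.index.name = "otu_id"
    lineages = {oid: Lineage.from_string(lin) for oid, lin, _ in rows}
    return OtuTable(marker=marker, counts=counts, lineages=lineages)


PLANT = "k__Viridiplantae;p__Streptophyta;c__Magnoliopsida;o__;f__;g__{g};s__"
BIRD = "k__Animalia;p__Chordata;c__Aves;o__Passeriformes;f__{f};g__{g};s__{s}"


@pytest.fixture
def plant_table():
    """Two hosts, three genera; designed so one edge falls below the filter."""
    return make_otu_table(
        "rbcL",
        [
            ("o1", PLANT.format(g="GenA"), [150, 4000]),
            ("o2", PLANT.format(g="GenB"), [90, 0]),
            ("o3", PLANT.format(g="GenC"), [20, 30]),
        ],
        ["s1", "s2"],
    )


@pytest.fixture
def assigned_samples():
    return [
        SampleMeta("s1", datetime.date(2024, 6, 5), host_species="Host one", host_reads=500),
        SampleMeta("s2", datetime.date(2024, 6, 22), host_species="Host two", host_reads=700),
    ]


@pytest.fixture
def toy_network():
    return BipartiteNetwork(
        kind="diet_plant",
        bird_nodes={"Host one": 260, "Host two": 4030},
        resource_nodes={"GenA": 4150, "GenC": 50},
        edges=[("Host one", "GenA", 150.0), ("Host two", "GenA", 4000.0)],
    )


def random_network(rng, max_nodes=30):
    """Random bipartite network with at least one edge."""
    n_birds = int(rng.integers(1, max_nodes // 2 + 1))
    n_res = int(rng.integers(1, max_nodes // 2 + 1))
    birds = {f"bird{i}": float(rng.integers(1, 10_000)) for i in range(n_birds)}
    resources = {f"res{i}": float(rng.integers(1, 10_000)) for i in range(n_res)}
    edges = []
    for b in birds:
        for r in resources:
            if rng.random() < 0.4:
                edges.append((b, r, float(rng.integers(1, 5_000))))
    if not edges:
        b, r = next(iter(birds)), next(iter(resources))
        edges.append((b, r, float(rng.integers(1, 5_000))))
    connected_b = {b for b, _, _ in edges}
    connected_r = {r for _, r, _ in edges}
    return BipartiteNetwork(
        kind="diet_plant",
        bird_nodes={b: a for b, a in birds.items() if b in connected_b},
        resource_nodes={r: a for r, a in resources.items() if r in connected_r},
        edges=sorted(edges),
    )
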