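"""Bipartite network data model, components, matrix I/O and generators.

A mutualistic network has two disjoint guilds: guild A, the *passive*
species (plants, matrix rows), and guild B, the *active* species
(pollinators or seed dispersers, matrix columns).  Edges only ever join
one guild to the other; weights, when present, are positive interaction
strengths.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import MatrixParseError, NetworkValidationError

logger = logging.getLogger(__name__)

Node = Hashable

GUILD_A = "A"
GUILD_B = "B"


def _label_key(node: Node) -> str:
    # deterministic order for arbitrary hashable labels
    return str(node)


@dataclass(frozen=True)
class BipartiteNetwork:
    """An undirected bipartite interaction network.

    Parameters
    ----------
    guild_a : frozenset
        Plant (passive) node labels.
    guild_b : frozenset
        Animal (active) node labels.
    edges : frozenset of (plant, animal) tuples
        Inter-guild links, stored with the plant first.
    weights : dict or None
        Optional edge -> positive interaction strength.  ``None`` marks a
        binary network.
    """

    guild_a: frozenset
    guild_b: frozenset
    edges: frozenset
    weights: Mapping | None = None

    # -- basic views ---------------------------------------------------
    @property
    def nodes(self) -> frozenset:
        return self.guild_a | self.guild_b

    @property
    def n_plants(self) -> int:
        return len(self.guild_a)

    @property
    def n_animals(self) -> int:
        return len(self.guild_b)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def is_weighted(self) -> bool:
        return self.weights is not None

    def guild_of(self, node: Node) -> str:
        if node in self.guild_a:
            return GUILD_A
        if node in self.guild_b:
            return GUILD_B
        raise KeyError(f"unknown node {node!r}")

    def degree(self, node: Node) -> int:
        self.guild_of(node)  # raises on unknown node
        return sum(1 for e in self.edges if node in e)

    def degrees(self) -> dict:
        d = {n: 0 for n in self.nodes}
        for a, b in self.edges:
            d[a] += 1
            d[b] += 1
        return d

    def neighbors(self, node: Node) -> frozenset:
        guild = self.guild_of(node)
        if guild == GUILD_A:
            return frozenset(b for a, b in self.edges if a == node)
        return frozenset(a for a, b in self.edges if b == node)

    def to_graph(self) -> nx.Graph:
        """Materialize as a networkx graph (isolated nodes included)."""
        g = nx.Graph()
        g.add_nodes_from(self.guild_a, bipartite=0)
        g.add_nodes_from(self.guild_b, bipartite=1)
        if self.weights is not None:
            g.add_edges_from(
                (a, b, {"weight": self.weights[(a, b)]}) for a, b in self.edges
            )
        else:
            g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class ComponentView:
    """Connected components of a (possibly node-deleted) network.

    ``node_subsets`` partitions every remaining node (isolated nodes are
    singleton components); ``gc_nodes`` is the largest — "giant" —
    component, with ties resolved toward the component containing the
    lexicographically smallest label so results are deterministic.
    """

    node_subsets: tuple
    gc_nodes: frozenset
    gc_size: int


def build_network(
    plant_ids: Sequence,
    animal_ids: Sequence,
    edges: Iterable,
    weights: Mapping | None = None,
) -> BipartiteNetwork:
    """Validate and assemble a :class:`BipartiteNetwork`.

    Raises
    ------
    NetworkValidationError
        On duplicate ids, intra-guild edges, unknown endpoints, duplicate
        edges, or non-positive weights.
    """
    plants = list(plant_ids)
    animals = list(animal_ids)
    seen: set = set()
    for nid in [*plants, *animals]:
        if nid in seen:
            raise NetworkValidationError(f"duplicate node id {nid!r}")
        seen.add(nid)
    set_a, set_b = frozenset(plants), frozenset(animals)

    oriented = []
    for u, v in edges:
        if u in set_a and v in set_b:
            e = (u, v)
        elif v in set_a and u in set_b:
            e = (v, u)
        elif u in set_a and v in set_a or u in set_b and v in set_b:
            raise NetworkValidationError(f"intra-guild edge ({u!r}, {v!r})")
        else:
            bad = u if u not in seen else v
            raise NetworkValidationError(f"edge ({u!r}, {v!r}) references unknown id {bad!r}")
        oriented.append(e)
    if len(set(oriented)) != len(oriented):
        dupes = {e for e in oriented if oriented.count(e) > 1}
        raise NetworkValidationError(f"duplicate edges: {sorted(map(str, dupes))}")
    edge_set = frozenset(oriented)

    wmap = None
    if weights is not None:
        wmap = {}
        for (u, v), w in weights.items():
            e = (u, v) if (u, v) in edge_set else (v, u)
            if e not in edge_set:
                raise NetworkValidationError(f"weight given for non-edge ({u!r}, {v!r})")
            if not w > 0:
                raise NetworkValidationError(f"non-positive weight {w} on edge {e!r}")
            wmap[e] = float(w)
        missing = edge_set - wmap.keys()
        if missing:
            raise NetworkValidationError(f"missing weights for edges {sorted(map(str, missing))}")
    return BipartiteNetwork(set_a, set_b, edge_set, wmap)


def binarize(net: BipartiteNetwork) -> BipartiteNetwork:
    """Drop interaction weights; any positive weight counts as a link."""
    if net.weights is None:
        return net
    return BipartiteNetwork(net.guild_a, net.guild_b, net.edges, None)


def components(net: BipartiteNetwork, removed: Iterable = ()) -> ComponentView:
    """Connected components of the graph induced on nodes minus ``removed``."""
    removed = frozenset(removed)
    unknown = removed - net.nodes
    if unknown:
        raise NetworkValidationError(f"removed set contains unknown nodes {sorted(map(str, unknown))}")
    g = net.to_graph()
    g.remove_nodes_from(removed)
    comps = [frozenset(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), min(_label_key(n) for n in c)))
    if comps:
        gc = comps[0]
    else:
        gc = frozenset()
    return ComponentView(tuple(comps), gc, len(gc))


def read_interaction_matrix(source, dialect: str = "weboflife") -> BipartiteNetwork:
    """Read a web-of-life style interaction matrix.

    First row holds animal (column) labels — the first header cell is
    ignored — and the first column holds plant (row) labels.  A cell
    value > 0 is a link carried as its weight; 0 or empty means no link.
    """
    if dialect != "weboflife":
        raise ValueError(f"unknown dialect {dialect!r}")
    if isinstance(source, str) and "\n" not in source:
        with open(source, "r", encoding="utf-8") as fh:
            return read_interaction_matrix(fh, dialect)
    if isinstance(source, str):
        source = io.StringIO(source)
    try:
        df = pd.read_csv(source, index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - delegated parse failure
        raise MatrixParseError(f"could not read CSV: {exc}") from exc
    if df.empty and df.columns.empty:
        raise MatrixParseError("empty interaction matrix")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise MatrixParseError(f"duplicate row labels: {dupes}")
    cols = [str(c) for c in df.columns]
    if len(set(cols)) != len(cols) or any(c.endswith(tuple(f".{i}" for i in range(1, 10))) and c.rsplit(".", 1)[0] in cols for c in cols):
        # pandas mangles duplicate header labels to name.1, name.2, ...
        base = [c.rsplit(".", 1)[0] if c.rsplit(".", 1)[-1].isdigit() else c for c in cols]
        dupes = sorted({b for b in base if base.count(b) > 1})
        raise MatrixParseError(f"duplicate column labels: {dupes}")

    plants = [str(r) for r in df.index]
    animals = cols
    edges, weights = [], {}
    for i, p in enumerate(plants):
        for j, a in enumerate(animals):
            raw = df.iat[i, j]
            if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() == "":
                continue
            try:
                val = float(raw)
            except ValueError:
                raise MatrixParseError(
                    f"non-numeric cell {raw!r} at row {p!r}, column {a!r}"
                ) from None
            if val < 0:
                raise MatrixParseError(f"negative cell {val} at row {p!r}, column {a!r}")
            if val > 0:
                edges.append((p, a))
                weights[(p, a)] = val
    isolated = [n for n in plants + animals if not any(n in e for e in edges)]
    if isolated:
        logger.info("retaining %d isolated species (all-zero rows/columns): %s",
                    len(isolated), isolated)
    return build_network(plants, animals, edges, weights)


def write_interaction_matrix(net: BipartiteNetwork, target) -> None:
    """Write the network back as a web-of-life style CSV matrix."""
    plants = sorted(net.guild_a, key=_label_key)
    animals = sorted(net.guild_b, key=_label_key)
    mat = pd.DataFrame(0.0, index=plants, columns=animals)
    for (p, a) in net.edges:
        mat.loc[p, a] = net.weights[(p, a)] if net.weights else 1.0
    mat.index.name = ""
    mat.to_csv(target)


def write_edge_list(net: BipartiteNetwork, target) -> None:
    """Edge-list TSV with columns node_a, node_b, weight."""
    rows = [
        {"node_a": a, "node_b": b,
         "weight": net.weights[(a, b)] if net.weights else 1.0}
        for a, b in sorted(net.edges, key=lambda e: (_label_key(e[0]), _label_key(e[1])))
    ]
    pd.DataFrame(rows, columns=["node_a", "node_b", "weight"]).to_csv(
        target, sep="\t", index=False)


def write_node_table(net: BipartiteNetwork, target) -> None:
    """Node CSV with columns node, guild, degree."""
    deg = net.degrees()
    rows = [
        {"node": n, "guild": net.guild_of(n), "degree": deg[n]}
        for n in sorted(net.nodes, key=_label_key)
    ]
    pd.DataFrame(rows, columns=["node", "guild", "degree"]).to_csv(target, index=False)


def fixture_fig3() -> BipartiteNetwork:
    """The worked seed-disperser example: Santa Bárbara, Sierra de Baza.

    Five plants, four thrush species and eleven links.  Plants 1 and 2
    are generalists connected to every disperser; plants 3–5 are
    specialists hanging off a single bird each.
    """
    edges = [
        ("pl1", "disp1"), ("pl1", "disp2"), ("pl1", "disp3"), ("pl1", "disp4"),
        ("pl2", "disp1"), ("pl2", "disp2"), ("pl2", "disp3"), ("pl2", "disp4"),
        ("pl3", "disp2"),
        ("pl4", "disp1"),
        ("pl5", "disp1"),
    ]
    return build_network(
        [f"pl{i}" for i in range(1, 6)],
        [f"disp{i}" for i in range(1, 5)],
        edges,
    )


def generate_bipartite(
    n_plants: int,
    n_animals: int,
    connectance: float,
    nestedness_bias: float = 0.0,
    seed: int = 0,
) -> BipartiteNetwork:
    """Random bipartite network with a tunable generalist core.

    Exactly ``round(connectance * n_plants * n_animals)`` edges (at least
    one) are drawn without replacement.  With ``nestedness_bias = 0``
    every plant–animal pair is equally likely; with bias 1 the sampling
    probability of pair (i, j) is proportional to the product of
    rank-ordered propensities, so low-rank nodes become generalists and
    a nested core–periphery structure emerges.
    """
    if not 0 < connectance <= 1:
        raise ValueError(f"connectance must be in (0, 1], got {connectance}")
    if not 0 <= nestedness_bias <= 1:
        raise ValueError(f"nestedness_bias must be in [0, 1], got {nestedness_bias}")
    if n_plants < 1 or n_animals < 1:
        raise ValueError("guild sizes must be >= 1")
    rng = np.random.default_rng(seed)
    # linearly decreasing propensity by rank; rank 0 is the top generalist
    r = (n_plants - np.arange(n_plants)) / n_plants
    s = (n_animals - np.arange(n_animals)) / n_animals
    w = (1.0 - nestedness_bias) + nestedness_bias * np.outer(r, s)
    p = (w / w.sum()).ravel()
    total = n_plants * n_animals
    m = max(1, round(connectance * total))
    chosen = rng.choice(total, size=m, replace=False, p=p)
    edges = [(f"pl{i // n_animals + 1}", f"an{i % n_animals + 1}") for i in chosen]
    return build_network(
        [f"pl{i}" for i in range(1, n_plants + 1)],
        [f"an{j}" for j in range(1, n_animals + 1)],
        edges,
    )
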