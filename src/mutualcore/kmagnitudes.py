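"""The three k-magnitudes: k-radius, k-degree and k-risk.

For a node *m* of guild A with opposite-guild innermost shell N^B:

* ``k_radius(m)`` — mean unweighted shortest-path distance from *m* to
  the members of N^B.  It measures compactness: how close a species sits
  to the generalist nucleus of its partner guild.  Unreachable targets
  (nodes outside the giant component) make the mean infinite.
* ``k_degree(m)`` — sum over the binary neighbors *j* of 1/k_radius(j).
  A fine-grained degree: each partner contributes more the closer it is
  to the innermost shell.  A neighbor with infinite k-radius contributes
  0 (the 1/inf limit).
* ``k_risk(m)`` — sum of shell differences to neighbors in strictly
  lower shells, plus ``epsilon * shell(m)`` to break ties between
  shells.  It scores how much damage losing *m* would inflict on
  species that depend on it for their route to the nucleus.

All three are computed on the binarized network; hop-count shortest
paths, never weight-modulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import pandas as pd

from .kcore import ShellAssignment, innermost_shell, kshell_decomposition
from .network import GUILD_A, GUILD_B, BipartiteNetwork, binarize

DEFAULT_EPSILON = 0.01


@dataclass(frozen=True)
class KMagnitudesTable:
    """Per-node k-shell, k-radius, k-degree and k-risk."""

    frame: pd.DataFrame  # index: node; columns: guild, kshell, kradius, kdegree, krisk
    epsilon: float

    def row(self, node) -> pd.Series:
        return self.frame.loc[node]

    def to_csv(self, target) -> None:
        out = self.frame.reset_index(names="node")
        out.to_csv(target, index=False)


def _all_radii(net: BipartiteNetwork, assignment: ShellAssignment) -> dict:
    """k-radius for every node, via one BFS per innermost-shell target."""
    g = binarize(net).to_graph()
    radii = {}
    for guild, opposite in ((GUILD_A, GUILD_B), (GUILD_B, GUILD_A)):
        members = assignment.guild_nodes(guild)
        if not members:
            continue
        targets = innermost_shell(assignment, opposite)
        dist_sum = {n: 0.0 for n in members}
        reach_count = {n: 0 for n in members}
        for t in targets:
            lengths = nx.single_source_shortest_path_length(g, t)
            for n in members:
                if n in lengths:
                    dist_sum[n] += lengths[n]
                    reach_count[n] += 1
        for n in members:
            if reach_count[n] == len(targets):
                radii[n] = dist_sum[n] / len(targets)
            else:
                radii[n] = math.inf
    return radii


def k_radius(net: BipartiteNetwork, assignment: ShellAssignment, node) -> float:
    """Mean shortest-path distance to the opposite guild's innermost shell."""
    guild = net.guild_of(node)
    opposite = GUILD_B if guild == GUILD_A else GUILD_A
    targets = innermost_shell(assignment, opposite)
    g = binarize(net).to_graph()
    lengths = nx.single_source_shortest_path_length(g, node)
    total = 0.0
    for t in targets:
        if t not in lengths:
            return math.inf
        total += lengths[t]
    return total / len(targets)


def k_degree(net: BipartiteNetwork, radii: Mapping, node) -> float:
    """Sum of reciprocal partner k-radii over the node's binary neighbors."""
    total = 0.0
    for j in net.neighbors(node):
        r = radii[j]
        if math.isfinite(r):
            total += 1.0 / r
    return total


def k_risk(
    net: BipartiteNetwork,
    assignment: ShellAssignment,
    node,
    epsilon: float = DEFAULT_EPSILON,
) -> float:
    """Shell-difference sum over lower-shell partners plus the epsilon tie-break."""
    if epsilon < 0:
        raise ValueError(f"epsilon must be >= 0, got {epsilon}")
    own = assignment.shell_of[node]
    total = sum(
        own - assignment.shell_of[j]
        for j in net.neighbors(node)
        if assignment.shell_of[j] < own
    )
    return total + epsilon * own


def compute_all(
    net: BipartiteNetwork, epsilon: float = DEFAULT_EPSILON
) -> KMagnitudesTable:
    """Full pipeline: binarize, decompose, then all three magnitudes per node."""
    if epsilon < 0:
        raise ValueError(f"epsilon must be >= 0, got {epsilon}")
    bnet = binarize(net)
    assignment = kshell_decomposition(bnet)
    radii = _all_radii(bnet, assignment)
    rows = {}
    for node in sorted(bnet.nodes, key=str):
        rows[node] = {
            "guild": bnet.guild_of(node),
            "kshell": assignment.shell_of[node],
            "kradius": radii[node],
            "kdegree": k_degree(bnet, radii, node),
            "krisk": k_risk(bnet, assignment, node, epsilon),
        }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "node"
    frame["kshell"] = frame["kshell"].astype(int)
    return KMagnitudesTable(frame, epsilon)
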