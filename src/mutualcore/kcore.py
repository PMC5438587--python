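"""k-shell decomposition of the bipartite graph.

The decomposition treats the network as a single undirected graph (both
guilds together, binary links).  The k-core is the maximal subgraph in
which every node keeps degree >= k; a node's shell index is the largest
k for which it survives in the k-core.  The classic implementation is
the Batagelj–Zaveršnik degree-pruning algorithm; we delegate to
``networkx.core_number`` which implements it.

The "innermost shell" of a guild — the nucleus of generalists the
k-magnitudes are measured against — is taken at the *per-guild* maximum
shell index, so it is non-empty whenever the guild has a node even if
that guild is absent from the global top core.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import networkx as nx

from .network import GUILD_A, GUILD_B, BipartiteNetwork, binarize


@dataclass(frozen=True)
class ShellAssignment:
    """Node -> k-shell index mapping with guild bookkeeping.

    Isolated nodes sit in shell 0 so that every node has a shell and the
    downstream magnitudes stay total.
    """

    shell_of: Mapping
    guild_a: frozenset
    guild_b: frozenset
    max_k: int
    max_k_by_guild: Mapping

    def shell(self, node) -> int:
        return self.shell_of[node]

    def guild_nodes(self, guild: str) -> frozenset:
        if guild == GUILD_A:
            return self.guild_a
        if guild == GUILD_B:
            return self.guild_b
        raise ValueError(f"unknown guild {guild!r}")


def kshell_decomposition(net: BipartiteNetwork) -> ShellAssignment:
    """Iterative-pruning core decomposition on the binarized network."""
    g = binarize(net).to_graph()
    shells = nx.core_number(g) if g.number_of_nodes() else {}
    max_k = max(shells.values(), default=0)
    by_guild = {
        GUILD_A: max((shells[n] for n in net.guild_a), default=0),
        GUILD_B: max((shells[n] for n in net.guild_b), default=0),
    }
    return ShellAssignment(dict(shells), net.guild_a, net.guild_b, max_k, by_guild)


def innermost_shell(assignment: ShellAssignment, guild: str) -> frozenset:
    """Nodes of ``guild`` sitting at that guild's maximum shell index."""
    members = assignment.guild_nodes(guild)
    if not members:
        raise ValueError(f"guild {guild!r} has no nodes")
    top = assignment.max_k_by_guild[guild]
    return frozenset(n for n in members if assignment.shell_of[n] == top)
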