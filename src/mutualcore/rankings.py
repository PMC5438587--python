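"""Static species rankings: k-risk, k-degree, degree, eigenvector, MusRank.

All rankings are computed once on the intact network (the static
assumption: no re-ranking during extinction sequences).  Ties are
reported explicitly as tie groups and are *not* broken here — shuffling
tied species is the extinction module's job.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConvergenceError
from .kmagnitudes import DEFAULT_EPSILON, compute_all
from .network import GUILD_A, GUILD_B, BipartiteNetwork, binarize

INDEX_NAMES = ("krisk", "kdegree", "degree", "eigenvector", "musrank")
BOTH_GUILDS = "both_guilds"
ANIMALS_ONLY = "animals_only"

#: tolerance under which two scores count as tied
TIE_TOL = 1e-12


@dataclass(frozen=True)
class Ranking:
    """An index name, per-node scores, the descending order and tie groups."""

    index_name: str
    scores: Mapping
    order: tuple
    tie_groups: tuple  # tuple of tuples, each a maximal run of equal scores
    scope: str

    def restricted_to(self, keep) -> "Ranking":
        """Filter to a node subset, preserving order and tie structure."""
        keep = frozenset(keep)
        groups = tuple(
            tuple(n for n in g if n in keep)
            for g in self.tie_groups
        )
        groups = tuple(g for g in groups if g)
        order = tuple(n for g in groups for n in g)
        scores = {n: self.scores[n] for n in order}
        return Ranking(self.index_name, scores, order, groups, self.scope)


def _make_ranking(index_name: str, scores: dict, scope: str) -> Ranking:
    order = sorted(scores, key=lambda n: (-scores[n], str(n)))
    groups: list[list] = []
    for n in order:
        if groups and abs(scores[groups[-1][-1]] - scores[n]) <= TIE_TOL:
            groups[-1].append(n)
        else:
            groups.append([n])
    return Ranking(
        index_name, scores, tuple(order), tuple(map(tuple, groups)), scope
    )


def degree_scores(net: BipartiteNetwork) -> dict:
    return {n: float(d) for n, d in binarize(net).degrees().items()}


def eigenvector_scores(net: BipartiteNetwork, tol: float = 1e-10,
                       max_iter: int = 100000) -> dict:
    """Principal-eigenvector centrality of the binary bipartite adjacency.

    Power iteration on the full undirected graph (no one-mode
    projection), normalized so the maximum entry is 1.
    """
    if not net.edges:
        raise ValueError("eigenvector centrality undefined on an edge-free network")
    nodes = sorted(net.nodes, key=str)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    adj = np.zeros((n, n))
    for a, b in net.edges:
        adj[idx[a], idx[b]] = 1.0
        adj[idx[b], idx[a]] = 1.0
    # bipartite spectra are symmetric (+/- lambda), which makes plain power
    # iteration oscillate; shifting by +I keeps the principal eigenvector
    # and makes the dominant eigenvalue unique in magnitude
    x = np.ones(n) / math.sqrt(n)
    for _ in range(max_iter):
        y = adj @ x + x
        norm = np.linalg.norm(y)
        if norm == 0:  # pragma: no cover - impossible with >=1 edge
            break
        y /= norm
        if np.abs(y - x).max() < tol * np.abs(y).max():
            x = y
            break
        x = y
    else:  # pragma: no cover
        raise ConvergenceError("power iteration did not converge",
                               last_iterate=x, n_iter=max_iter)
    x = np.abs(x)
    x /= x.max()
    return {node: float(x[idx[node]]) for node in nodes}


def musrank_scores(
    net: BipartiteNetwork, tol: float = 1e-10, max_iter: int = 10000
) -> tuple[dict, dict]:
    """MusRank importance (animals) and vulnerability (plants).

    The nonlinear fitness–complexity style map: starting from all-ones,

        I_i <- sum_j M_ij V_j
        V_j <- 1 / sum_i M_ij (1 / I_i)

    with both vectors renormalized to mean 1 after each step, iterated
    until the maximum relative change drops below ``tol``.  The harmonic
    mean makes a plant's vulnerability dominated by its *least*
    important partner, which is what lets the index find animals that
    prop up fragile specialists.  Degree-0 species cannot take part in
    the map (the vulnerability update would divide by zero) and are
    assigned score 0.
    """
    bnet = binarize(net)
    animals = sorted((a for a in bnet.guild_b if bnet.degree(a) > 0), key=str)
    plants = sorted((p for p in bnet.guild_a if bnet.degree(p) > 0), key=str)
    importance = {a: 0.0 for a in bnet.guild_b}
    vulnerability = {p: 0.0 for p in bnet.guild_a}
    if not animals or not plants:
        return importance, vulnerability

    a_idx = {a: i for i, a in enumerate(animals)}
    p_idx = {p: j for j, p in enumerate(plants)}
    m = np.zeros((len(animals), len(plants)))
    for p, a in bnet.edges:
        m[a_idx[a], p_idx[p]] = 1.0

    imp = np.ones(len(animals))
    vul = np.ones(len(plants))
    for it in range(1, max_iter + 1):
        new_imp = m @ vul
        new_imp = np.clip(new_imp, 1e-300, None)
        new_vul = 1.0 / (m.T @ (1.0 / imp))
        new_imp /= new_imp.mean()
        new_vul /= new_vul.mean()
        delta = max(
            np.abs((new_imp - imp) / new_imp).max(),
            np.abs((new_vul - vul) / new_vul).max(),
        )
        imp, vul = new_imp, new_vul
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"MusRank did not converge in {max_iter} iterations",
            last_iterate=(imp, vul), n_iter=max_iter,
        )
    importance.update({a: float(imp[a_idx[a]]) for a in animals})
    vulnerability.update({p: float(vul[p_idx[p]]) for p in plants})
    return importance, vulnerability


def rank_by(
    net: BipartiteNetwork,
    index_name: str,
    scope: str = BOTH_GUILDS,
    epsilon: float = DEFAULT_EPSILON,
) -> Ranking:
    """Score every in-scope species by ``index_name`` and rank descending."""
    if index_name not in INDEX_NAMES:
        raise ValueError(f"unknown index {index_name!r}; choose from {INDEX_NAMES}")
    if scope not in (BOTH_GUILDS, ANIMALS_ONLY):
        raise ValueError(f"unknown scope {scope!r}")
    if index_name == "musrank":
        if scope != ANIMALS_ONLY:
            raise ValueError("musrank ranks active species only; use scope animals_only")
        importance, _ = musrank_scores(net)
        return _make_ranking(index_name, importance, ANIMALS_ONLY)

    if index_name == "degree":
        scores = degree_scores(net)
    elif index_name == "eigenvector":
        scores = eigenvector_scores(net)
    else:
        table = compute_all(net, epsilon=epsilon).frame
        scores = table[index_name].to_dict()
    if scope == ANIMALS_ONLY:
        scores = {n: s for n, s in scores.items() if n in net.guild_b}
    return _make_ranking(index_name, scores, scope)


def ranking_table(ranking: Ranking, net: BipartiteNetwork) -> pd.DataFrame:
    """Export view: node, guild, index, score, rank, tie_group_id."""
    rows = []
    rank = 1
    for gid, group in enumerate(ranking.tie_groups):
        for node in group:
            rows.append({
                "node": node,
                "guild": net.guild_of(node),
                "index": ranking.index_name,
                "score": ranking.scores[node],
                "rank": rank,
                "tie_group_id": gid,
            })
        rank += len(group)
    return pd.DataFrame(rows, columns=["node", "guild", "index", "score", "rank", "tie_group_id"])
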