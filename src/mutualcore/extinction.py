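"""Static extinction procedures and their performance statistics.

Two procedures, both using a ranking computed once on the intact
network (no rewiring, no re-ranking):

* **mixed** — one species removed per step, highest score first,
  regardless of guild.  The damage proxy is the fraction of the
  original giant component (GC) still connected; the procedure stops as
  soon as that fraction drops to 0.5 or below.  Performance is the
  percentage of species removed to get there — lower is a more
  efficient (more destructive) ranking.

* **primary_animals** — only animals are removed (primary extinctions);
  a plant that loses its last partner is a secondary extinction.  Both
  the surviving-plant fraction and the GC fraction are tracked at every
  step until all animals are gone, and each curve is summarized by its
  trapezoidal area under the curve (AUC) over the removed-animal
  fraction — lower AUC means faster destruction.

Ties in a ranking are resolved by shuffling within each tie group;
repetitions use independent RNG streams derived from (base seed, index
name, repetition number) so any single sequence can be reproduced in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import mean
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .network import BipartiteNetwork, binarize, components
from .rankings import ANIMALS_ONLY, BOTH_GUILDS, INDEX_NAMES, Ranking, rank_by

PROCEDURE_MIXED = "mixed"
PROCEDURE_PRIMARY = "primary_animals"

# fixed per-index stream identifiers for seed derivation
_INDEX_STREAM = {name: i + 1 for i, name in enumerate(INDEX_NAMES)}


@dataclass(frozen=True)
class ExtinctionStep:
    removed_count: int
    removed_fraction: float
    gc_fraction: float
    surviving_plant_fraction: float | None = None
    removed_node: object = None


@dataclass(frozen=True)
class ExtinctionTrajectory:
    steps: tuple
    procedure: str
    rep_seed: int

    @property
    def gc_fractions(self) -> tuple:
        return tuple(s.gc_fraction for s in self.steps)

    @property
    def surviving_plant_fractions(self) -> tuple:
        return tuple(s.surviving_plant_fraction for s in self.steps)


@dataclass(frozen=True)
class ExperimentSummary:
    index_name: str
    procedure: str
    n_reps: int
    per_rep_values: tuple
    metric: str  # removal_pct_to_half_gc | auc_plants | auc_gc

    @property
    def mean_value(self) -> float:
        return mean(self.per_rep_values)

    @property
    def sd(self) -> float:
        return float(np.std(self.per_rep_values, ddof=1)) if self.n_reps > 1 else 0.0


def _rep_rng(base_seed: int, index_name: str, rep: int) -> np.random.Generator:
    return np.random.default_rng([base_seed, _INDEX_STREAM[index_name], rep])


def _gc_size(g: nx.Graph) -> int:
    # an isolated species is not a functioning component: only components
    # carrying at least one interaction count toward the GC
    return max((len(c) for c in nx.connected_components(g) if len(c) > 1),
               default=0)


def shuffled_order(ranking: Ranking, rng: np.random.Generator) -> list:
    """Rank order with each tie group independently, uniformly shuffled."""
    order = []
    for group in ranking.tie_groups:
        group = list(group)
        if len(group) > 1:
            rng.shuffle(group)
        order.extend(group)
    return order


def auc(xs: Sequence[float], ys: Sequence[float]) -> float:
    """Trapezoidal area under an extinction curve over x in [0, 1].

    The curve must start at the intact network: xs[0] = 0 with ys[0] = 1.
    """
    xs, ys = list(xs), list(ys)
    if len(xs) != len(ys) or len(xs) < 2:
        raise ValueError("xs and ys must have equal length >= 2")
    if any(b <= a for a, b in zip(xs, xs[1:])):
        raise ValueError("xs must be strictly increasing")
    if xs[0] != 0 or ys[0] != 1:
        raise ValueError("curve must start at (0, 1): the intact network")
    return float(np.trapezoid(ys, xs))


def run_mixed_extinction(
    net: BipartiteNetwork,
    ranking: Ranking,
    gc_threshold: float = 0.5,
    n_reps: int = 100,
    seed: int = 0,
    keep_trajectories: bool = False,
) -> ExperimentSummary | tuple:
    """Procedure 1: remove species of either guild until the GC halves.

    Returns the ``removal_pct_to_half_gc`` summary; with
    ``keep_trajectories=True`` also the per-repetition trajectories.
    """
    if not 0 < gc_threshold < 1:
        raise ValueError(f"gc_threshold must be in (0, 1), got {gc_threshold}")
    if ranking.scope != BOTH_GUILDS:
        raise ValueError("mixed procedure needs a both-guild ranking")
    bnet = binarize(net)
    gc0 = components(bnet).gc_size
    if gc0 == 0:
        raise ValueError("network has an empty giant component")
    n_species = len(bnet.nodes)
    base_graph = bnet.to_graph()

    values, trajectories = [], []
    for rep in range(n_reps):
        rng = _rep_rng(seed, ranking.index_name, rep)
        order = shuffled_order(ranking, rng)
        g = base_graph.copy()
        steps = [ExtinctionStep(0, 0.0, 1.0)]
        removed = 0
        for node in order:
            g.remove_node(node)
            removed += 1
            frac = _gc_size(g) / gc0
            steps.append(ExtinctionStep(removed, removed / n_species, frac,
                                        removed_node=node))
            if frac <= gc_threshold:
                break
        values.append(removed / n_species * 100.0)
        if keep_trajectories:
            trajectories.append(
                ExtinctionTrajectory(tuple(steps), PROCEDURE_MIXED, rep))
    summary = ExperimentSummary(ranking.index_name, PROCEDURE_MIXED, n_reps,
                                tuple(values), "removal_pct_to_half_gc")
    return (summary, trajectories) if keep_trajectories else summary


def run_primary_extinction(
    net: BipartiteNetwork,
    ranking: Ranking,
    n_reps: int = 100,
    seed: int = 0,
) -> tuple:
    """Procedure 2: remove all animals in rank order, track both curves.

    Returns ``(auc_plants summary, auc_gc summary, trajectories)``.  A
    both-guild ranking is filtered to animals preserving relative order.
    Plants isolated in the intact network never lose a partner, so they
    are not counted as secondary extinctions.
    """
    bnet = binarize(net)
    if not bnet.guild_b:
        raise ValueError("network has no animal species to remove")
    animal_ranking = (ranking if ranking.scope == ANIMALS_ONLY
                      else ranking.restricted_to(bnet.guild_b))
    if set(animal_ranking.order) != set(bnet.guild_b):
        raise ValueError("ranking does not cover every animal species")

    gc0 = components(bnet).gc_size
    if gc0 == 0:
        raise ValueError("network has an empty giant component")
    n_plants = bnet.n_plants
    n_animals = bnet.n_animals
    degrees0 = bnet.degrees()
    linked_plants = frozenset(p for p in bnet.guild_a if degrees0[p] > 0)
    base_graph = bnet.to_graph()

    auc_plant_vals, auc_gc_vals, trajectories = [], [], []
    for rep in range(n_reps):
        rng = _rep_rng(seed, animal_ranking.index_name, rep)
        order = shuffled_order(animal_ranking, rng)
        g = base_graph.copy()
        steps = [ExtinctionStep(0, 0.0, 1.0, surviving_plant_fraction=1.0)]
        xs, gc_ys, plant_ys = [0.0], [1.0], [1.0]
        for removed, animal in enumerate(order, start=1):
            g.remove_node(animal)
            gc = _gc_size(g)
            # secondary extinction: an initially-linked plant at degree 0
            extinct = sum(1 for p in linked_plants if g.degree(p) == 0)
            surv = (n_plants - extinct) / n_plants if n_plants else 1.0
            x = removed / n_animals
            steps.append(ExtinctionStep(removed, x, gc / gc0,
                                        surviving_plant_fraction=surv,
                                        removed_node=animal))
            xs.append(x)
            gc_ys.append(gc / gc0)
            plant_ys.append(surv)
        auc_plant_vals.append(auc(xs, plant_ys))
        auc_gc_vals.append(auc(xs, gc_ys))
        trajectories.append(
            ExtinctionTrajectory(tuple(steps), PROCEDURE_PRIMARY, rep))
    plants_summary = ExperimentSummary(
        animal_ranking.index_name, PROCEDURE_PRIMARY, n_reps,
        tuple(auc_plant_vals), "auc_plants")
    gc_summary = ExperimentSummary(
        animal_ranking.index_name, PROCEDURE_PRIMARY, n_reps,
        tuple(auc_gc_vals), "auc_gc")
    return plants_summary, gc_summary, trajectories


def compare_rankings(
    net: BipartiteNetwork,
    indexes: Iterable[str],
    procedure: str = PROCEDURE_MIXED,
    gc_threshold: float = 0.5,
    n_reps: int = 100,
    seed: int = 0,
    epsilon: float = 0.01,
) -> pd.DataFrame:
    """Run one procedure under several rankings and flag the winner.

    Returns a table with one row per (index, metric); the winner of each
    metric is the index with the smallest mean (most destructive).  The
    base seed is shared, but each (index, repetition) pair draws from
    its own derived stream, so results do not depend on evaluation
    order.  MusRank only ranks active species and is rejected for the
    mixed procedure.
    """
    indexes = list(dict.fromkeys(indexes))
    if not indexes:
        raise ValueError("no ranking indexes given")
    if procedure not in (PROCEDURE_MIXED, PROCEDURE_PRIMARY):
        raise ValueError(f"unknown procedure {procedure!r}")
    if procedure == PROCEDURE_MIXED and "musrank" in indexes:
        raise ValueError("musrank is not valid for the mixed extinction procedure")

    summaries: list[ExperimentSummary] = []
    for name in indexes:
        if procedure == PROCEDURE_MIXED:
            ranking = rank_by(net, name, BOTH_GUILDS, epsilon=epsilon)
            summaries.append(run_mixed_extinction(
                net, ranking, gc_threshold=gc_threshold, n_reps=n_reps, seed=seed))
        else:
            scope = ANIMALS_ONLY if name == "musrank" else BOTH_GUILDS
            ranking = rank_by(net, name, scope, epsilon=epsilon)
            plants_s, gc_s, _ = run_primary_extinction(
                net, ranking, n_reps=n_reps, seed=seed)
            summaries.extend([plants_s, gc_s])

    rows = [{
        "index": s.index_name, "procedure": s.procedure, "metric": s.metric,
        "mean": s.mean_value, "sd": s.sd, "n_reps": s.n_reps,
    } for s in summaries]
    table = pd.DataFrame(rows)
    table["winner"] = False
    for metric, group in table.groupby("metric"):
        best = group["mean"].min()
        table.loc[group.index[group["mean"] == best], "winner"] = True
    return table


def trajectories_table(trajectories: Iterable[ExtinctionTrajectory]) -> pd.DataFrame:
    """Export view: rep, step, removed_node, removed_fraction, gc_fraction, surviving_plant_fraction."""
    rows = []
    for traj in trajectories:
        for i, s in enumerate(traj.steps):
            rows.append({
                "rep": traj.rep_seed, "step": i, "removed_node": s.removed_node,
                "removed_fraction": s.removed_fraction,
                "gc_fraction": s.gc_fraction,
                "surviving_plant_fraction": s.surviving_plant_fraction,
            })
    return pd.DataFrame(rows, columns=["rep", "step", "removed_node",
                                       "removed_fraction", "gc_fraction",
                                       "surviving_plant_fraction"])
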