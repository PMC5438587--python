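"""Summary statistics and figure-style outputs.

* degree vs k-degree scaling: least squares through the origin for the
  model k_degree = alpha * degree,
* winner tables tallying which ranking index wins each
  (network, metric) group,
* extinction-curve plotting as a convenience layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .extinction import ExperimentSummary, ExtinctionTrajectory
from .kmagnitudes import KMagnitudesTable


@dataclass(frozen=True)
class ScalingFit:
    alpha: float
    n_points: int
    residual_norm: float


def fit_kdegree_scaling(table: KMagnitudesTable, degrees: Mapping) -> ScalingFit:
    """Fit k_degree = alpha * degree by least squares through the origin.

    alpha = sum(d * kd) / sum(d^2) over nodes with finite k-degree.
    """
    d = np.array([degrees[n] for n in table.frame.index], dtype=float)
    kd = table.frame["kdegree"].to_numpy(dtype=float)
    finite = np.isfinite(kd)
    d, kd = d[finite], kd[finite]
    denom = float((d * d).sum())
    if denom == 0:
        raise ValueError("cannot fit scaling: all degrees are zero")
    alpha = float((d * kd).sum()) / denom
    residual = float(np.linalg.norm(kd - alpha * d))
    return ScalingFit(alpha, int(len(d)), residual)


def winner_table(records: Iterable[tuple]) -> tuple[pd.DataFrame, pd.Series]:
    """Tally per-(network, metric) winners across experiment summaries.

    ``records`` is an iterable of ``(network_id, ExperimentSummary)``.
    Returns the per-group table (with a ``shared`` flag when several
    indexes tie on the minimal mean) and per-index win counts; a shared
    win counts once for every tied index.
    """
    records = list(records)
    if not records:
        raise ValueError("no summaries supplied")
    rows = [{
        "network": net_id, "metric": s.metric, "index": s.index_name,
        "mean": s.mean_value,
    } for net_id, s in records]
    frame = pd.DataFrame(rows)
    out_rows = []
    for (net_id, metric), group in sorted(frame.groupby(["network", "metric"]),
                                          key=lambda kv: (str(kv[0][0]), kv[0][1])):
        best = group["mean"].min()
        winners = sorted(group.loc[group["mean"] == best, "index"])
        for w in winners:
            out_rows.append({
                "network": net_id, "metric": metric, "winner": w,
                "mean": best, "shared": len(winners) > 1,
            })
    table = pd.DataFrame(out_rows, columns=["network", "metric", "winner", "mean", "shared"])
    counts = table["winner"].value_counts().sort_index()
    counts.name = "wins"
    return table, counts


def plot_extinction_curves(trajectories: Iterable[ExtinctionTrajectory],
                           path, curve: str = "gc") -> None:
    """Plot averaged extinction curves to ``path`` (convenience, untested)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    trajectories = list(trajectories)
    fig, ax = plt.subplots(figsize=(5, 4))
    for traj in trajectories:
        xs = [s.removed_fraction for s in traj.steps]
        if curve == "gc":
            ys = [s.gc_fraction for s in traj.steps]
        else:
            ys = [s.surviving_plant_fraction for s in traj.steps]
        ax.plot(xs, ys, alpha=0.25, color="steelblue")
    ax.set_xlabel("removed fraction")
    ax.set_ylabel("giant component fraction" if curve == "gc"
                  else "surviving plant fraction")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
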