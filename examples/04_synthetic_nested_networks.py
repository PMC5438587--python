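"""Ranking comparison across a batch of synthetic nested networks.

Generates 10 nested bipartite networks (30 plants x 30 animals,
connectance 0.1, full nestedness bias), runs the mixed extinction
procedure under four rankings on each, and tallies which index halves
the giant component with the fewest removals per network.
"""

import mutualcore as mc

records = []
for seed in range(10):
    net = mc.generate_bipartite(30, 30, 0.1, 1.0, seed=seed)
    table = mc.compare_rankings(
        net, ["krisk", "kdegree", "degree", "eigenvector"],
        procedure=mc.PROCEDURE_MIXED, n_reps=25, seed=seed)
    for _, row in table.iterrows():
        records.append((f"net{seed:02d}", mc.ExperimentSummary(
            row["index"], row["procedure"], row["n_reps"],
            (row["mean"],), row["metric"])))

per_group, wins = mc.winner_table(records)
print(per_group.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print("\nwins per index (shared wins count for every tied index):")
print(wins.to_string())

print(
    "\nEach row is one network's winner: the ranking whose mean removal "
    "percentage to halve the giant component was lowest over 25 "
    "tie-shuffled repetitions."
)
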