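"""Mixed-guild extinction race on the worked network.

Removes species of either guild in ranking order until the giant
component halves, 100 tie-shuffled repetitions per index, and compares
how few removals each ranking needs — lower means the index finds the
structurally critical species faster.
"""

import mutualcore as mc

net = mc.fixture_fig3()
table = mc.compare_rankings(
    net,
    ["krisk", "kdegree", "degree", "eigenvector"],
    procedure=mc.PROCEDURE_MIXED,
    gc_threshold=0.5,
    n_reps=100,
    seed=1,
)
print(table.to_string(index=False, float_format=lambda v: f"{v:.2f}"))

print(
    "\n'mean' is the percentage of the 9 species removed before the "
    "giant component drops to half its original size. k-risk needs only "
    "2 of 9 species (22.22%) in every repetition; rankings whose top "
    "scores tie across several species pay for unlucky shuffles."
)
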