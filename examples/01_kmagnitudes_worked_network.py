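"""k-magnitudes of the built-in seed-dispersal network.

Builds the 5-plant / 4-thrush network from Santa Bárbara (Sierra de
Baza), decomposes it into k-shells and prints the per-species table:
shell index, k-radius (mean hop distance to the partner guild's
innermost shell), k-degree (sum of reciprocal partner radii) and
k-risk (shell-difference sum plus the 0.01 tie-break).
"""

import mutualcore as mc

net = mc.fixture_fig3()
print(f"{net.n_plants} plants, {net.n_animals} dispersers, {net.n_edges} links\n")

table = mc.compute_all(net, epsilon=0.01)
print(table.frame.to_string(float_format=lambda v: f"{v:.2f}"))

print(
    "\nThe four birds and the two generalist plants form the 2-shell "
    "nucleus; radius 2.5 marks the peripheral plants three hops from "
    "most of it. disp1 tops k-risk (2.02): it alone props up the two "
    "specialist plants, so losing it drags them down with it."
)
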