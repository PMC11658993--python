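"""Desynchronize a synchronously oscillating six-node network.

At external inputs (1, 0.4) the six delay-coupled nodes oscillate in near
synchrony (mean Kuramoto order parameter ~0.75).  Minimizing the
cross-correlation cost with a negative weight actively rewards
decorrelated activity; the optimized control drives the order parameter
far below the uncontrolled baseline.
"""

from oscontrol.tasks import six_node_synchrony_task

res, R_controlled, R_uncontrolled = six_node_synchrony_task(
    "desync", "cross_correlation")

print(f"uncontrolled Kuramoto mean R = {R_uncontrolled:.3f}")
print(f"controlled   Kuramoto mean R = {R_controlled:.3f}")
print(f"control energy F_E           = {res.F_E:.1f}")
print("\nR ranges from 0 (no phase synchrony) to 1 (full synchrony); the")
print("control roughly quarters the network's phase coherence.")
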