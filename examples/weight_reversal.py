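"""Latency-driven reversal of synaptic drive on a slow connection.

The three input cells of the latency circuit are fired together at 5 Hz
with STDP on.  Connections A and B (delay 10 ms) and C (delay 15 ms, weaker)
all start with arrivals before the output spike, so all potentiate.  As A
and B strengthen, spike latency shortens and the output fires *before* C's
arrival: C's drive flips sign and its weight collapses — a rise-then-fall
trajectory produced purely by the latency mechanism.
"""

import numpy as np

from polychron import run_weight_reversal_demo

trace = run_weight_reversal_demo(duration_s=60)
a, b, c = trace.weights

print("sec   w(A)    w(B)    w(C)")
for s in range(0, 60, 4):
    print(f"{s:3d}  {a[s]:6.2f}  {b[s]:6.2f}  {c[s]:6.2f}")

peak = int(np.argmax(c))
print()
print(f"A and B end saturated at {a[-1]:.1f} / {b[-1]:.1f} mV.")
print(f"C rises from {c[0]:.1f} to {c.max():.2f} mV at t = {peak} s, "
      f"then falls to {c[-1]:.1f} mV as its arrivals land after the output spike.")
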