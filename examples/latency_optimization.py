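"""Expanding a downstream cell's input space by tuning spike latency.

In the six-cell circuit the target (index 5) needs near-coincident arrivals
from the latency cell (index 3) and an independent input (index 4, fixed at
offset 19 ms, delay 1 ms).  Whether they coincide depends on the latency
cell's firing time, which can be shifted by changing one afferent weight
(connection 0->3, swept over 1..10 mV).  For each delay on the 3->5
connection, the optimised map marks a timing pattern active if *any* weight
step makes the target fire — spike latency turns a fixed wiring into a
tunable delay line.
"""

from polychron import optimize_latency

results = optimize_latency()

print("3->5 delay   non-optimised   optimised")
total_non = total_opt = 0
for delay, (non_opt, opt) in results.items():
    print(f"{delay:10d}   {non_opt.n_active:13d}   {opt.n_active:9d}")
    total_non += non_opt.n_active
    total_opt += opt.n_active
print(f"{'total':>10}   {total_non:13d}   {total_opt:9d}")
print()
print("Every optimised map contains its non-optimised counterpart, and the")
print("weight sweep strictly enlarges the total active input space: tuning")
print("the latency cell's drive brings otherwise-missed timing patterns")
print("into coincidence at the target.")
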