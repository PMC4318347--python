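"""Weight regulation at a single synapse.

Two RS cells joined by one plastic synapse (initial weight 6 mV, hard cap
15 mV) are driven with bursts of pre-before-post spike pairs — sustained
positive synaptic drive.  Without metaplasticity the weight climbs to the
cap and stays there; with the metaplastic threshold (r=0.1, p=0.05) the
growing resistance term raises theta, suppresses LTP, and holds the weight
below the cap for the whole 100 s run.
"""

from polychron import run_single_synapse_demo

on = run_single_synapse_demo(metaplasticity=True)
off = run_single_synapse_demo(metaplasticity=False)

print("sec   theta    weight(meta)  weight(no meta)")
for s in range(0, 101, 10):
    print(f"{on.seconds[s]:4d}  {on.theta[s]:+.3f}   {on.weight[s]:12.2f}  {off.weight[s]:15.2f}")

print()
print(f"max weight with metaplasticity   : {on.weight.max():.2f} mV  (cap 15.0)")
print(f"max weight without metaplasticity: {off.weight.max():.2f} mV")
print()
print("With metaplasticity the weight stabilises below the hard cap; the")
print("threshold theta settles at a small positive value that balances")
print("potentiation against the boosted depression.")
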