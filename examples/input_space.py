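"""The active input space of a convergently driven cell.

The six-cell circuit's middle cell (index 3) receives three inputs through
delays (10, 10, 15) with all weights at the 10 mV cap.  Every combination
of input firing times over a 0-20 ms range is tested in an independent
250 ms frame; the map is drawn in difference coordinates (t1-t2, t2-t3),
which removes translated duplicates.  Two coincident arrivals suffice to
fire the cell, so the active set forms three straight 'arms', one per pair
of inputs.
"""

from polychron import input_space_circuit, input_space_response

result = input_space_response(input_space_circuit(), target=3)

print(f"active cells: {result.n_active} of {result.active.size} "
      f"(difference grid {result.active.shape[0]}x{result.active.shape[1]})")
print()
step = 2
for i in range(0, result.diffs.size, step):
    row = "".join(
        "#" if result.active[i, j] else "."
        for j in range(0, result.diffs.size, step)
    )
    print(row)
print()
print("rows: t1-t2 from -20 (top) to +20; columns: t2-t3 from -20 to +20.")
print("The horizontal arm is t1=t2 (coincidence through the two 10 ms")
print("delays); the vertical arm is t2-t3=5 (10 ms vs 15 ms delay); the")
print("diagonal arm is t1-t3=5.")
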