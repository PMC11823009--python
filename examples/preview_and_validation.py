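"""Input validation and the ASCII field-map preview.

A small replicated design is first specified inconsistently (the fills list
is shorter than the replicate count, and the counts do not balance) to show
the validation messages, then corrected and rendered as the text map a crew
would carry: plot numbers for experimental cells, F for fills, W for
wheel-track cells, with the front range at the bottom.
"""

from plotgrid import ReplicatedSpec, build_matrix, render_preview, validate_spec

bad = ReplicatedSpec(plots_per_rep=10, reps=2, rows=4, ranges=6,
                     fills_after_reps=(2,), wheel_track_ranges=(3,))
print("Issues with the inconsistent spec:")
for issue in validate_spec(bad):
    print(f"  - {issue}")

good = ReplicatedSpec(plots_per_rep=9, reps=2, rows=4, ranges=6,
                      fills_after_reps=(1, 1), wheel_track_ranges=(3,))
print("\nCorrected spec validates:", validate_spec(good) == [])
print(render_preview(build_matrix(good)))
# The serpentine walk starts bottom-left, reverses on each range, passes
# straight through the wheel-track range (W) and places each replicate's
# fill (F) right after its last plot.
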