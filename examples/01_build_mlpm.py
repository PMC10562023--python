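"""Build an MLC leaf position map from a VMAT plan.

Generates a synthetic single-arc plan, writes it to DICOM, reads it back,
and turns the leaf trajectories into the 110x178 map the prediction network
consumes: rows are the retained leaves (bank A leaf 1 ... bank B leaf 60,
always-closed pairs removed), columns are control points, and every cell is
the leaf's distance in mm from its pair's closed coordinate.
"""

import tempfile
from pathlib import Path

from vmatqa import (
    PlanGenParams,
    build_leaf_matrix,
    build_mlpm,
    find_always_closed_pairs,
    generate_plan,
    read_rtplan,
    write_rtplan,
)

plan = generate_plan(PlanGenParams(seed=1))
with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "plan.dcm"
    write_rtplan(plan, path)
    plan = read_rtplan(path)

print(f"plan {plan.plan_id}: {plan.n_control_points} control points")

matrix = build_leaf_matrix(plan)
excluded = find_always_closed_pairs([matrix])
print(f"always-closed leaf pairs (excluded from the map): {sorted(excluded)}")

mlpm = build_mlpm(matrix, excluded, fixed_shape=(110, 178))
print(f"MLPM shape: {mlpm.shape}  (rows = 120 - 2 x {len(excluded)} excluded pairs)")
print(f"max leaf displacement from closed: {mlpm.values.max():.1f} mm")
print(f"fraction of exactly-closed cells: {(mlpm.values == 0).mean():.2f}")
# A large maximum displacement means wide apertures; a high closed fraction
# means little modulation - both are plan-complexity cues the CNN can read.
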