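"""Simulate one slow-migrating spheroid well and map its coverage.

Builds a 144 h recording for the slow phenotype preset, summarises it
per time point and prints the endpoint coverage map.  Covered counts
track how far cells have migrated; the per-electrode maxima (percent
relative impedance) track how much cell material sits on each
electrode.
"""

import numpy as np

from zspread import coverage_map, simulate_recording, summarize_well

rec = simulate_recording("slow", seed=1, well_id="W01")
ws = summarize_well(rec)

print("time (h)  covered  median max rel. impedance (%)")
for t, c, m in zip(ws.time_points_h, ws.covered_count, ws.median_max_rel_impedance):
    print(f"{t:7.0f}  {c:7d}  {m:10.1f}")

grid = coverage_map(rec, 144.0)
print("\nendpoint coverage map (rows x cols, %; '-' = uncovered):")
for row in grid:
    print(" ".join("   - " if np.isnan(v) else f"{v:5.0f}" for v in row))
print(
    f"\n{np.isfinite(grid).sum()} of 42 electrodes covered at 144 h "
    f"({np.isfinite(grid).mean() * 100:.0f}%)"
)
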