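"""Migration-vs-proliferation discrimination on reference wells.

Simulates the four reference groups (fast/slow phenotype, each with
and without proliferation suppression), calibrates the two quadrant
cuts, fits the PCA + fuzzy c-means reference model, then classifies
held-out intermediate-phenotype wells.  Expected outcome: the four
reference groups land in their four quadrants/clusters, and the
intermediate wells attach to a low-migration cluster.
"""

import numpy as np

from zspread import build_features, run_pipeline, simulate_recording

TRUTH = {
    "fast": (True, True),
    "fast+mitomycin": (True, False),
    "slow": (False, True),
    "slow+mitomycin": (False, False),
}

recs = []
i = 0
for label in TRUTH:
    for s in range(6):
        recs.append(simulate_recording(label, seed=10 * i + s, well_id=f"W{i:02d}-{s}"))
    i += 1
for s in range(4):
    recs.append(simulate_recording("intermediate", seed=900 + s, well_id=f"T{s}"))

result = run_pipeline(recs, reference_truth=TRUTH, seed=0)
thr = result.thresholds
print(
    f"calibrated cuts: migration >= {thr.coverage_cut:.1f} covered electrodes, "
    f"proliferation >= {thr.impedance_cut:.1f} % median max rel. impedance\n"
)

print("group                    endpoint quadrants      cluster label (majority)")
for label in list(TRUTH) + ["intermediate"]:
    sub = result.report[result.report["group"] == label]
    quads = sub["quadrant_at_endpoint"].value_counts().to_dict()
    clusters = sub["cluster_label"].value_counts().to_dict()
    print(f"{label:24s} {str(quads):22s} {clusters}")

memb = result.report[result.report["group"] == "intermediate"]
cols = [c for c in memb.columns if c.startswith("membership_")]
print("\nintermediate wells, mean cluster memberships:")
print(np.round(memb[cols].mean().to_numpy(), 3))
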