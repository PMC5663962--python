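"""Simulate a focal-follow study and write its input tables.

Generates a registry of core social groups (matriarchs, mothers, focal-aged
females, sisters, aunts, calves, bulls), focal follows with per-follow
aggregation membership, and affiliative interaction events drawn from the
negative-binomial model at known coefficients, then writes the three CSVs
plus a ground-truth manifest.
"""

from orphanbonds import SyntheticTruth, generate_dataset, write_dataset
from orphanbonds.focal_data_io import focal_statuses, sampling_summary

truth = SyntheticTruth(seed=42)
dataset = generate_dataset(truth)
write_dataset(dataset, "scratch/example_dataset")

statuses = focal_statuses(dataset.follows, dataset.registry)
n_orphans = sum(s.is_orphan for s in statuses.values())
print(f"individuals: {len(dataset.registry)}")
print(f"focal females: {len(statuses)} ({n_orphans} orphans)")
print(f"follows: {len(dataset.follows)}, interaction events: {len(dataset.interactions)}")
print()
print(sampling_summary(dataset.follows, statuses).round(2).to_string(index=False))
print()
print("Each row gives one activity/stratum cell: how many focals were sampled,")
print("the total observation hours, and the median (IQR) per-focal minutes and")
print("follow counts -- the sampling-effort format of a focal-follow study.")
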