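"""Generate a synthetic two-group resting-state dataset with known ground truth.

Builds a 90-region small-world substrate, weakens a compact 13-edge
subnetwork in the patient group, and samples band-limited (0.01-0.08 Hz,
TR 2 s) signals for 12 patients and 24 controls.
"""
import numpy as np

from connectotopo import SimulationConfig, make_ground_truth, simulate_timeseries
from connectotopo.io import write_timeseries_dir

gt = make_ground_truth(n_nodes=90, k=8, p=0.1, n_affected_edges=13,
                       effect_size=0.2, seed=7)
cfg = SimulationConfig(seed=1)
ts = simulate_timeseries(gt, cfg)
write_timeseries_dir(ts, "scratch_example_dataset", ground_truth=gt)

lesion_nodes = sorted({v + 1 for e in gt.affected_edges for v in e})
print(f"substrate: {gt.n_nodes} regions, {gt.n_edges} edges")
print(f"lesion: {len(gt.affected_edges)} edges on regions {lesion_nodes}")
print(f"subjects: {ts.n_subjects} ({len(ts.group_ids('patient'))} patients), "
      f"{ts.subjects[0].n_timepoints} volumes each at TR {ts.tr_seconds} s")
# The lesion regions are where every downstream stage should localise the
# group difference; effect_size 0.2 means each lesioned coupling loses
# about 0.2 units of Pearson correlation in patients.
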