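"""Brightness accommodation under repeated stimulation.

Runs the bundled `habituation` scenario — 55 trains (125 ms, 100 us,
200 Hz, 90 uA): 50 at 4 s intervals, then 5 at 200 s intervals — and
prints the per-train peak brightness relative to the first train.
"""
import numpy as np

from cortiphos import DynamicsParams, RunConfig, SimulatorSession
from cortiphos.io import build_scenario, stimulation_frames

pmap, stim, config = build_scenario("habituation")
run = RunConfig(resolution=(64, 64), dt=config["dt"], seed=1)
session = SimulatorSession(pmap, run=run,
                           dynamics=DynamicsParams(sigma_thr=0.0))
_, trace = session.run_sequence(stimulation_frames(stim), render=False,
                                record_trace=True)

arrays = trace.as_arrays()
bright = arrays["brightness"][:, 0]
activation = arrays["A"][:, 0]
amp = stim[:, 0, 0]
starts = np.flatnonzero((amp > 0) & (np.r_[0.0, amp[:-1]] == 0))
train_frames = int(np.ceil(0.125 / config["dt"]))
b_peaks = np.array([bright[s:s + train_frames].max() for s in starts])
a_peaks = np.array([activation[s:s + train_frames].max() for s in starts])

print(f"{len(starts)} trains; per-train peaks relative to the first train:")
print("  train   brightness   activation")
for i in (0, 1, 2, 5, 10, 49, 50, 52, 54):
    print(f"  {i + 1:4d}   {b_peaks[i] / b_peaks[0]:10.3e}  "
          f"{a_peaks[i] / a_peaks[0]:10.3e}")
print("\nThe slow memory trace accumulates with each train and subtracts from")
print("the drive: closely spaced trains fade until activation falls below the")
print("detection threshold (brightness 0).  During the final 200 s intervals")
print("the trace partially decays (time constant ~1970 s), so the peak")
print("activation recovers across trains 51-55.")
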