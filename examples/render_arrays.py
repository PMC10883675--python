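"""Render percepts from four Utah-style electrode arrays.

Builds the bundled `four_arrays` scenario (four 10x10 grids, 0.4 mm
spacing, right hemisphere) and runs one train at each of the three
stimulation amplitudes (40 / 80 / 120 uA).
"""
import numpy as np

from cortiphos import RunConfig, SimulatorSession, phosphene_size
from cortiphos.io import build_scenario, stimulation_frames

pmap, stim, config = build_scenario("four_arrays")
run = RunConfig(resolution=(128, 128), fov=config["fov_deg"],
                dt=config["dt"], seed=config["seed"])
session = SimulatorSession(pmap, run=run)
frames, trace = session.run_sequence(stimulation_frames(stim),
                                     record_trace=True)

amps = stim[:, 0, 0]
arrays = trace.as_arrays()
print(f"{len(pmap)} electrodes, {len(frames)} frames, "
      f"field positions x in [{pmap.x_deg.min():.2f}, {pmap.x_deg.max():.2f}] deg")
for amp in (40.0, 80.0, 120.0):
    i = int(np.flatnonzero(amps == amp)[-1])  # last frame of each train
    gated_on = int(np.count_nonzero(arrays["brightness"][i] > 0))
    sizes = phosphene_size(amp * 1e-6, pmap.r)
    print(f"  {amp:5.1f} uA : electrodes above threshold = {gated_on:3d}/400, "
          f"size = {sizes.min():.3f}-{sizes.max():.3f} deg, "
          f"peak pixel = {frames[i].image.max():.2e}")
print("\nHigher amplitudes drive more electrodes past their sampled detection")
print("thresholds and spread over more cortex (size ~ sqrt(I)); peripheral")
print("arrays give larger phosphenes (lower magnification), all in the left")
print("hemifield (right-hemisphere implant).  Absolute brightness stays far")
print("below half-maximum at these amplitudes under the published constants.")
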