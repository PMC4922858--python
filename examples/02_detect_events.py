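"""Detect binding events in noisy traces and compare with ground truth.

Events open when a trace rises 3.2 sigma above the baseline noise and
close when it falls back below 1 sigma (hysteresis thresholding, with
the baseline estimated by median/MAD per trace).
"""

import numpy as np

from splicekin import (AcquisitionConfig, detect_events, extract_dwells,
                       preset_scheme, render_traces, simulate_molecules)
from splicekin.io import truths_to_events

config = AcquisitionConfig()
truths = simulate_molecules(preset_scheme("50uM"), 100, config, seed=7)
traces = render_traces(truths, config, seed=8, channels=["U4"])

detected = []
for trace in traces:
    detected.extend(detect_events(trace))
truth_events = [e for e in truths_to_events(truths) if e.channel == "U4"]

dwells = extract_dwells(detected)
print(f"ground-truth U4 intervals : {len(truth_events)}")
print(f"detected U4 events        : {len(detected)} "
      f"({sum(e.censored for e in detected)} censored at 60 min)")
print(f"mean detected dwell       : {np.mean(dwells):.1f} s")
# the detected count falls short of truth for two reasons: sub-frame
# events (dwell < 3 s) can fall between exposures, and the rare stalled
# B complexes of this low-ATP regime occupy most of the recording, which
# defeats a per-trace robust baseline (>50% bound frames). Both losses
# also affect the real experiment's threshold analysis.
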