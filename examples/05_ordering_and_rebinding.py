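"""Order of NTC arrival versus U4 release, and U4 rebinding.

On the activation pathway the NTC joins after U4 release, so the
per-molecule offset delta = t(U4 release) - t(NTC arrival) is negative.
A shuffled control (NTC arrival times permuted across molecules) shows
what the histogram would look like if the two were unrelated.
"""

import numpy as np

from splicekin import (AcquisitionConfig, classify_outcomes,
                       match_coincident, ordering_offsets, preset_scheme,
                       randomized_control, rebinding_analysis,
                       simulate_molecules)
from splicekin.io import truths_to_events

truths = simulate_molecules(preset_scheme("2mM"), 300,
                            AcquisitionConfig(), seed=21)
events = truths_to_events(truths)
u4 = [e for e in events if e.channel == "U4"]
u5 = [e for e in events if e.channel == "U5"]
ntc = [e for e in events if e.channel == "NTC"]

rec = ordering_offsets(u4, ntc)
ctrl = randomized_control(u4, ntc, n_shuffles=50, seed=22)
print(f"molecules with both a U4 release and an NTC arrival: "
      f"{rec.deltas.size} (excluded: {rec.n_excluded})")
print(f"fraction with NTC arriving after U4 release (delta < 0): "
      f"{100 * rec.fraction_negative:.1f}%")
print(f"shuffled control: {100 * ctrl.fraction_negative:.1f}% negative")
print(f"median delay from U4 release to NTC arrival: "
      f"{-np.median(rec.deltas):.0f} s")
# the observed offsets pile up just below zero (NTC arrives ~30 s after
# U4 release); the control spreads over the whole recording.

pairs, _, _ = match_coincident(u4, u5, 3.0)
classify_outcomes(pairs, 3.0)
reb = rebinding_analysis(pairs, u4, 3.0, background_rate_per_min=2.3e-3)
print(f"\nU4 reappearance while U5 persists: {reb.n_rebinding} of "
      f"{reb.n_eligible} activation events ({reb.percent:.1f}%)")
# U4 release is irreversible in the generative scheme, so reappearances
# here are zero; in the real experiment the rare observed reappearances
# are comparable to the nonspecific background binding rate, which this
# simulation does not inject at occupied locations.
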