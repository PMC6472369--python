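"""Theta-gamma phase-amplitude coupling quantified per minute.

Injects a gamma carrier whose amplitude follows the theta phase (depth 0.5),
then measures the Tort modulation index over the whole session and in 1-min
bins, plus a circular-shift surrogate control.
"""

import numpy as np

from thetalink.pac import bandpass_phase_amp, modulation_index, pac_timecourse
from thetalink.simulate import BandSource, PACSpec, SharedSourceSpec, generate_lfp_pair

spec = SharedSourceSpec(
    bands=(BandSource(8.0, 4.0, 4.0, 1.0, 0.7),),
    noise_power_a=0.25,
    noise_power_b=0.25,
)
recording = generate_lfp_pair(
    spec, PACSpec(f_theta=8.0, f_gamma=40.0, carrier_amp=2.0, depth=0.5),
    duration_s=300.0, seed=5,
)

phase, amplitude = bandpass_phase_amp(recording, "dHipp")
full = modulation_index(phase, amplitude)
surrogate = modulation_index(phase, np.roll(amplitude, 2000))
print(f"modulation index (whole session): {full.mi:.2e}")
print(f"surrogate (2-s amplitude shift) : {surrogate.mi:.2e}")

print("\nper-minute modulation index:")
for res in pac_timecourse(recording, "dHipp"):
    print(f"  bin at {res.bin_onset:5.0f} s: MI = {res.mi:.2e} ({res.n_cycles:.0f} theta cycles)")
print(
    "\nStationary coupling gives a flat MI time course well above the "
    "shift surrogate, which destroys the phase-amplitude relationship."
)
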