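"""Y-maze spatial novelty preference with novelty-locked theta coherence.

Simulates a test phase in which the animal prefers the novel arm (80%) and
theta coupling is elevated during novel-arm bouts, then recovers both from
tracking and LFP.
"""

import pandas as pd

from thetalink.behavior import arm_bouts, preference_ratio, speed_control
from thetalink.coherence import band_coherence, epoch_coherence
from thetalink.dataio import EpochTable
from thetalink.simulate import generate_ymaze_session

recording, tracking, arm_polygons = generate_ymaze_session(
    pref_target=0.8, seed=11, novel_theta_gain=1.8
)

bouts = arm_bouts(tracking, arm_polygons, min_bout_s=1.0)
ratio = preference_ratio(bouts, window=(0.0, 60.0))
print(f"first-minute preference ratio : {ratio:.2f}  (chance = 0.50)")
print("mean running speed per arm (cm/s):")
print(speed_control(bouts).round(1).to_string())

epochs = EpochTable(
    bouts.rename(columns={"arm": "label"})[["onset", "offset", "label"]]
)
pooled = epoch_coherence(recording, epochs, "dHipp", "PFC", label_field="label")
rows = {
    arm: band_coherence(pooled[arm], (6.0, 12.0))[1]  # peak theta coherence
    for arm in ("novel", "familiar")
    if arm in pooled
}
print("\npeak theta dHipp-PFC coherence by arm:")
print(pd.Series(rows).round(3).to_string())
print(
    "\nNovel-arm bouts carry the injected coherence elevation; running "
    "speeds stay matched, so the contrast is not a locomotion artifact."
)
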