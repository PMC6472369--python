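"""T-maze working memory: decision-zone coherence and its link to accuracy.

Simulates a rewarded-alternation session (7 blocks x 10 trials) whose
hippocampal-prefrontal coupling strengthens in the choice phase, extracts
the last 1.2 s before each decision-zone exit, and contrasts sample- vs
choice-phase band coherence.
"""

from thetalink.behavior import decision_epochs, swm_performance
from thetalink.coherence import band_coherence, epoch_coherence, fractional_change
from thetalink.simulate import generate_tmaze_session

recording, _, trials = generate_tmaze_session(
    p_correct=0.85, n_trials=10, blocks=7, seed=7, choice_gain=1.4
)

per_block, average = swm_performance(trials, last_blocks=4)
print("per-block accuracy :", per_block.round(2).to_dict())
print(f"last-4-block mean  : {average:.2f}")

epochs = decision_epochs(trials, window_s=1.2)
pooled = epoch_coherence(recording, epochs, "dHipp", "PFC")
sample = band_coherence(pooled["sample"], (6.0, 12.0))[0]
choice = band_coherence(pooled["choice"], (6.0, 12.0))[0]
print(f"\nmean theta coherence, sample phase : {sample:.3f}")
print(f"mean theta coherence, choice phase : {choice:.3f}")
print(f"fractional change (choice-sample)/sample: {fractional_change(choice, sample):+.3f}")
print(
    "\nThe injected choice-phase coupling gain appears as a positive "
    "fractional coherence change, the per-animal predictor used in the "
    "performance regressions."
)
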