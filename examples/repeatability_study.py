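"""Five-trial intra-observer repeatability study with operator noise.

Each trial re-places every ligament attachment point with 0.25 mm Gaussian
placement noise (a fresh seed per trial), rebuilds the model, runs the
battery and averages strains.  Each of the 48 cell series is regressed on
trial index; a cell is 'repeatable' when the slope is not significantly
different from zero at the 5% level.
"""

from sijstrain import (
    OperatorNoiseModel,
    make_canonical_pelvis,
    repeatability_report,
    run_trials,
)

lm = make_canonical_pelvis()
noise = OperatorNoiseModel(sd=0.25, seed=42)
grids = run_trials(lm, noise, n_trials=5)
report = repeatability_report(grids, alpha=0.05)

print(f"operator noise sd = {noise.sd} mm, 5 trials, 48 regressions")
print(f"repeatable cells: {report.n_repeatable}/48 "
      f"(fraction {report.fraction_repeatable:.3f})")

frame = report.to_frame()
failing = frame[~frame["repeatable"]]
if len(failing):
    print("\ncells rejecting the zero-slope (repeatability) hypothesis:")
    print(failing[["scenario", "group", "side", "slope", "p_value"]].to_string(index=False))
else:
    print("\nno cell rejected the zero-slope hypothesis")
print("\nUnder pure placement noise with no systematic drift, about 5% of")
print("cells are expected to reject by chance at alpha = 0.05.")
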