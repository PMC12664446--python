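"""Train the obstruction detector on a small simulated dataset and score it.

A micro version of the fixed-parameter experiment: simulate obstructed and
clean frames at N0 = 400 and 2 mmol/ml, train the (single-scale) U-Net,
and report the metrics at the 0.5 operating threshold.  Desk-scale counts
keep this example in the minutes range on a laptop CPU; raise them toward
800/400/400 (or the reference 2500/2500/2500) for headline numbers.
"""

from shuntscope import PhantomSpec, build_valve_phantom
from shuntscope.evaluate import desk_detector_schedule, run_fixed_experiment

volume = build_valve_phantom(PhantomSpec())
schedule = desk_detector_schedule(seed=0, epochs_a=110, epochs_b=15)

result = run_fixed_experiment(volume, n_train=400, n_test_obstructed=50,
                              n_test_clean=50, detector_config=schedule,
                              n_angles=90, seed=1)

print(f"trained {len(result.loss_trace)} epochs, "
      f"final BCE {result.loss_trace[-1]:.4f}")
row = result.report.at_threshold(0.5)
print(f"threshold 0.5 on {result.report.n_obstructed} obstructed / "
      f"{result.report.n_clean} clean test frames:")
print(f"  mean per-pixel sensitivity : {row['mean_sensitivity']:.3f}")
print(f"  mean detection precision   : {row['mean_precision']:.3f}")
print(f"  median Dice coefficient    : {row['median_dsc']:.3f}")
print(f"  frame false-positive rate  : {row['fpr']:.3f}")
# Sensitivity: fraction of true obstruction pixels found; precision:
# fraction of detected pixels that are real; FPR: fraction of clean frames
# with any detection at all.  At this reduced training scale the numbers
# sit well below the desk-scale run's; see scripts/acceptance.py for that.
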