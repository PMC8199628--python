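"""Full protocol: 5-fold cross-validated accuracy versus window length.

Runs the whole pipeline (segment -> features -> windows -> per-fold
scaler+classifier) on a noisy simulated cohort for both tasks and prints
pooled accuracy as the window grows from 1 to 4 steps.  Accuracy rises
with the number of consecutive steps a decision may observe.
"""

import tawagait as tg

trials = tg.simulate_cohort(tg.SimConfig(n_subjects=4, n_trials_per_activity=5,
                                         noise_level=0.4, seed=2))
ks = [1, 2, 4]
config = tg.TrainConfig(epochs=150, seed=2)

for task in ("activity", "pedestrian"):
    reports = tg.run_protocol(trials, task, ks, train_config=config, seed=2)
    accs = "  ".join(
        f"k={k}: {reports[k].pooled_metrics['accuracy']:.3f}" for k in ks)
    print(f"{task:<10} pooled accuracy  {accs}")

report = tg.run_protocol(trials, "activity", [2], train_config=config, seed=2)[2]
print("\npooled confusion matrix, activity task, k=2 "
      "(rows true, cols predicted; 1=descent, 2=ascent, 3=level walk):")
print(report.pooled_confusion)
# Pooled metrics concatenate all five test folds; each fold's model and
# scaler were fitted on that fold's training trials only.
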