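"""Leave-one-subject-out evaluation of the multitask CNN.

Each fold trains on all subjects but one and scores the held-out subject
at the equal-sensitivity/specificity operating point; tremor-free
subjects contribute context metrics only. Prints the per-task summary and
the Hanley standard error of the mean tremor AUC.
"""

import resttremor as rt
from resttremor.models import TrainConfig
from resttremor.evaluation import hanley_auc_se, run_loso

script = rt.default_visit_script(n_cycles=2)
cohort = rt.simulate_cohort(n_subjects=5, class_mix={0: 1, 1: 2, 2: 2},
                            seed=0, script=script)
ws = rt.build_window_set([rec for _, _, rec, _ in cohort.visits])

config = TrainConfig(learning_rate=0.0046, max_epochs=20,
                     early_stop_patience=10, seed=0)
report = run_loso(rt.multitask_fft_spec(), ws, config, n_repeats=1)

print(report.summary().round(3).to_string())
df = report.to_frame()
mean_auc = df[df.task == "tremor"].auc.mean()
n_pos = int((ws.tremor_label == 1).sum())
n_neg = int((ws.tremor_label == 0).sum())
se = hanley_auc_se(mean_auc, n_pos, n_neg)
print(f"\nmean tremor AUC {mean_auc:.3f} "
      f"(Hanley SE {se:.4f} at {n_pos} tremor / {n_neg} non-tremor windows)")
print("AUC ~1.0 reflects the cleanly separable synthetic cohort, not "
      "clinical difficulty.")
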