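"""Train the condition classifier on a reduced synthetic experiment.

Runs the full chain — generate condition-labelled recordings, select the most
active electrodes, build 1-Hz power-density features per 10-s fragment, train
a random forest on a stratified 70/30 split — at a reduced scale (30
fragments per class, 12 electrodes, 2 kHz) so it finishes in well under a
minute. The full-scale experiment (300 fragments per class, 60 electrodes at
10 kHz) is what scripts/acceptance.py runs.
"""

import json

from aliflow.pipeline import RunConfig, condition_classification_experiment

config = RunConfig(
    seed=1,
    fragments_per_class=30,
    mixture_fragments=60,
    n_electrodes=12,
    n_select=8,
    fs=2000.0,
    n_active=6,
    n_estimators=200,
)
result = condition_classification_experiment(config)
report = result["report"]

print(f"held-out accuracy          : {report.accuracy:.3f}")
print(f"five-fold CV accuracies    : {[round(s, 3) for s in report.cv_scores]}")
print(f"confidence upon prediction : {report.cup:.3f}")
print("class repartition on the held-out set (rows = true condition):")
print(json.dumps(report.class_repartition, indent=2))

mix = result["mixture"]
print("\ncomposite-condition fragments (generated as a CTL/GW/EV mixture "
      f"with weights {mix['weights']}):")
print("  assigned :", {k: round(v, 3) for k, v in mix["repartition"].items()})
print("  truth    :", {k: round(v, 3) for k, v in mix["true_fragment_fractions"].items()})
print("  chi-square vs uniform assignment:",
      f"stat={mix['chi2']['statistic']:.1f}, p={mix['chi2']['pvalue']:.2e}")
print("(the classifier recovers the mixing weights fragment by fragment, and "
      "the chi-square rejects the random-assignment hypothesis of 33.3% per class)")
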