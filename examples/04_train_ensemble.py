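"""Train the stacked withdrawal-prediction ensemble.

Per seed: balanced 80/10/10 split, train-set min-max normalization, four
view-specific base classifiers, then a KNN meta-classifier (57 neighbours,
distance weights) trained on the pooled base probabilities over
train + test1 and evaluated on the held-out test2 segment. Three seeds
here for speed; the full protocol repeats over seeds 0-9.
"""

import dataclasses

from watchtox import generate, run_watch_repeated, strong_signal_config
from watchtox.ensemble import VIEW_ORDER

bundle = generate(dataclasses.replace(strong_signal_config(seed=0), n_drugs=300))
results, summary = run_watch_repeated(
    bundle.drugs, bundle.activities, bundle.profiles, seeds=range(3)
)

print("per-view accuracy on test1 (mean over seeds):")
for v in VIEW_ORDER:
    print(f"  {v.value:<16} {summary[f'{v.value}_accuracy_mean']:.3f}")
print(f"\naveraging baseline accuracy (test2): {summary['baseline_accuracy_mean']:.3f}")
print(f"ensemble accuracy (test2):           {summary['ensemble_accuracy_mean']:.3f}"
      f" +/- {summary['ensemble_accuracy_sd']:.3f}")
print(f"ensemble MCC (test2):                {summary['ensemble_mcc_mean']:.3f}")
# The meta-classifier should not be worse than its best input view; MCC in
# [-1, 1] summarizes the whole confusion matrix on the balanced test set.
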