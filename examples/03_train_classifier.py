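"""Train the three-class random forest on pipeline-generated examples.

Labeled examples come from the full pipeline: synthetic scenes are
segmented, described, and matched against their ground-truth label
points — so training data inherit real segmentation imperfections.
"""

import numpy as np

from seedpheno import DESCRIPTOR_NAMES, ForestConfig, save_bundle, train
from seedpheno.pipeline import make_training_examples

examples = make_training_examples(600, rng_seed=42)
bundle, report = train(examples, ForestConfig())  # 100 trees, depth 7

print(f"examples: {len(examples)}  held-out accuracy: {report.accuracy:.3f}"
      f"  OOB: {report.oob_score:.3f}")
print("confusion (rows true, cols predicted; normal/partial/full):")
print(report.confusion)
order = np.argsort(report.feature_importance)[::-1][:5]
print("top-5 feature importances:")
for i in order:
    print(f"  {DESCRIPTOR_NAMES[i]:16s} {report.feature_importance[i]:.3f}")
save_bundle(bundle, "model.bundle")
print("saved model.bundle")
# The partially collapsed class typically shows the lowest recall: it is
# an intermediate phenotype sharing features with both neighbours.
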