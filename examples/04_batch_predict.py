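"""Batch-score a directory of images with a trained model.

Writes annotated PNGs, a per-seed parameter table and per-image summary
spreadsheets, exactly as the command line `seedpheno predict` would.
"""

import pandas as pd

from seedpheno import ForestConfig, SceneSpec, run_predict, train, write_fixture_set
from seedpheno.pipeline import make_training_examples

bundle, _ = train(make_training_examples(300, rng_seed=1), ForestConfig())

specs = [SceneSpec(n_seeds=40, cluster_fraction=0.2, image_size=(600, 800),
                   rng_seed=s) for s in (21, 22, 23)]
write_fixture_set(specs, "scenes")

status = run_predict("scenes", bundle, out_dir="scenes/out")
summary = pd.read_csv("scenes/out/seed_summary.csv")
print(f"exit status: {status}")
print(summary[["image_id", "total_seeds", "count_normal", "count_partial",
               "count_full", "mean_confidence"]].to_string(index=False))
# scenes/out/predicted_images/ holds the colour-coded contours
# (green = normal, orange = partial, red = full); seed_parameters.csv has
# one row per seed with all 38 descriptors and class probabilities.
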