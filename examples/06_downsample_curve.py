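"""How much training data does the classifier need?

Random class-stratified subsets of increasing size are drawn from a
training pool; each trains a forest with the final default parameters
and is scored on the pool and on an independent validation set.  The
plateau is the smallest size whose mean validation accuracy is within
0.1 percentage points of the next larger size.
"""

from seedpheno.classifier import downsample_curve
from seedpheno.pipeline import make_training_examples

examples = make_training_examples(900, rng_seed=9)
pool, validation = examples[:600], examples[600:]

table, plateau = downsample_curve(pool, validation,
                                  sizes=[50, 100, 200, 400, 600],
                                  iterations=5, base_seed=0)
means = table.groupby("size")[["acc_on_pool", "acc_on_validation"]].mean()
print(means.round(4).to_string())
print(f"\nplateau size (validation accuracy change < 0.1%): {plateau}")
# Accuracy rises steeply at small sizes and flattens once the forest has
# seen enough examples of each phenotype.
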