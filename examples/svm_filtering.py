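"""Codon-usage SVM: separating coding from non-coding reading frames.

Trains the filter on sequences drawn from a human-like codon-usage table
(positives) versus a uniform table (negatives), then shows how the
recovery of true coding sequence improves with test-sequence length —
short fragments simply carry too few codons for composition to speak.
"""

import numpy as np

from cdg.simulate import CODON_TABLES, make_cds
from cdg.svm import train_svm

rng = np.random.default_rng(3)
uniform = CODON_TABLES["uniform"]
# soften the human-like skew so the length effect is visible on screen
human = {c: 1.0 + w / 25 for c, w in CODON_TABLES["human_like"].items()}
positives = [make_cds(900, human, rng) for _ in range(300)]
negatives = [make_cds(900, uniform, rng) for _ in range(300)]

model = train_svm(positives, negatives, seed=3)
print(f"training: {model.n_pos} positives, {model.n_neg} negatives")
print(f"held-out accuracy {model.holdout_accuracy:.3f} "
      f"(sensitivity {model.holdout_sensitivity:.3f}, "
      f"specificity {model.holdout_specificity:.3f})")

print("\nsensitivity of true-coding recovery by sequence length:")
for length in (99, 300, 501, 798):
    test = [make_cds(length, human, rng) for _ in range(300)]
    sens = float(np.mean(model.predict(test)))
    print(f"  {length:4d} bp: {sens:.3f}")
print("Longer sequences average the codon-usage signal over more codons, "
      "so the classifier's recovery rate rises with length. At ~100 bp a "
      "frequency vector built from 33 codons is so noisy that the "
      "specificity-first threshold rejects essentially everything.")
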