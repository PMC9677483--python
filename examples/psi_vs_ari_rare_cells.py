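"""Why PSI: size-balanced scoring of rare-population clustering errors.

Two abundant and six rare populations are planted.  A prediction that
absorbs every rare population into the abundant clusters still gets most
point *pairs* right, so the pair-based ARI and information-based AMI stay
high — but six of eight cluster identities are lost, which the set-matching
PSI exposes.
"""

import numpy as np

from proxeval import (adjusted_mutual_information, adjusted_rand_index,
                      pair_sets_index)

sizes = [470, 410] + [20] * 6
truth = np.repeat(np.arange(8), sizes)

merged = truth.copy()
merged[truth >= 2] = truth[truth >= 2] % 2          # rare -> abundant
good = truth.copy()
bad_two = np.isin(truth, [6, 7])
good[bad_two] = truth[bad_two] % 2                  # only 2 rare types lost

for name, pred in [("6 of 8 types merged away", merged),
                   ("6 of 8 types recovered", good)]:
    print(f"{name:26s}  PSI={pair_sets_index(truth, pred):.2f}  "
          f"ARI={adjusted_rand_index(truth, pred):.2f}  "
          f"AMI={adjusted_mutual_information(truth, pred):.2f}")

print("\nARI/AMI barely separate the two outcomes; PSI does, because each"
      "\nmatched cluster contributes equally regardless of its size.")
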