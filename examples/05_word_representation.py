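"""Word over/under-representation scores.

C = (Obs - Exp)/Exp x 100%, with Exp the maximal-order Markov expectation
from the word's subword frequencies.  On i.i.d. sequence C is ~0; a tandem
repeat makes its unit word strongly overrepresented.  CpG suppression in
the human genome (published C = -76.37%) is the canonical real example.
"""

import numpy as np

import contextmut as cm

rng = np.random.default_rng(0)
iid = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=100_000)])
table = cm.count_words(iid, max_k=4)
print("i.i.d. sequence (scores should hover near 0):")
print(cm.score_words(table, ["CG", "ATAG", "ATTG", "ACAA", "CCA"]).to_string(index=False))

repeat = cm.count_words("CCA" * 2000 + iid[:40_000], max_k=3)
s = cm.representation_score("CCA", repeat)
print(f"\nCCA in a repeat-spiked sequence: {s}")

print("\npublished reference scores (percent deviation from expectation):")
print(cm.load_reference_representation().to_string(index=False))
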