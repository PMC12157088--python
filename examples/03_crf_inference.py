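"""Exact CRF inference on an enumerable toy instance.

Compares the forward algorithm's log-partition and Viterbi's best path
with brute-force enumeration over all label sequences, and shows the
path probabilities normalising to 1.
"""

import itertools

import numpy as np

from lexner.crf import crf_log_partition, crf_score, viterbi_decode

rng = np.random.default_rng(4)
n, L = 4, 3
P = rng.normal(size=(n, L))
T = rng.normal(size=(L, L))

scores = {Y: crf_score(P, T, list(Y)) for Y in itertools.product(range(L), repeat=n)}
logZ = crf_log_partition(P, T)
path, star = viterbi_decode(P, T)
best = max(scores, key=scores.get)

print(f"{L}^{n} = {len(scores)} label paths enumerated")
print(f"forward-algorithm logZ = {logZ:.6f}")
print(f"enumeration logsumexp  = {np.log(sum(np.exp(s) for s in scores.values())):.6f}")
print(f"viterbi path {path} score {star:.6f}; enumeration argmax {list(best)}")
print(f"sum of path probabilities: "
      f"{sum(np.exp(s - logZ) for s in scores.values()):.9f}")
# Both dynamic programs agree with enumeration; the probabilities sum to 1.
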