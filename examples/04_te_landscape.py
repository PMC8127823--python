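"""Transposable-element divergence landscape from a simulated family.

Pairwise per-cent identity between members of a TE family is a proxy for
the timing of expansion bursts: each burst leaves a peak in the identity
distribution.  This plants bursts at 87%, 93% and 98% (the salmon
Tc1-mariner landscape) and recovers them as a histogram.
"""

import numpy as np

from ohnofate import identity_histogram, pairwise_identity, simulate_te_family

names, seqs, truth = simulate_te_family(seed=2, length=3000)
matrix = pairwise_identity(seqs)
values = matrix[np.triu_indices(len(seqs), k=1)]

hist = identity_histogram(values, bin_width=1.0)
occupied = hist[hist["count"] > 0]
print("pairwise-identity histogram (occupied bins):")
print(occupied.to_string(index=False))

for burst, peak in truth.groupby("burst").peak.first().items():
    idx = [i for i, n in enumerate(names) if n.startswith(f"burst{burst}_")]
    within = matrix[np.ix_(idx, idx)][np.triu_indices(len(idx), 1)]
    print(f"burst {burst}: planted peak {peak:.0f}%, "
          f"observed within-burst mean {within.mean():.1f}%")
# Within-burst identities cluster tightly at the planted peaks; the lower
# off-peak mass comes from cross-burst comparisons.
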