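"""Shared helpers for the test suite."""

import numpy as np

from seqtrials.causal_tree import CausalTreeCounts


def random_counts(rng, n_scale=200):
    """A random strictly positive causal-tree count table."""
    y1 = rng.integers(9, n_scale, size=(2, 2, 2))
    y2 = np.zeros((2, 2, 2, 2, 2), dtype=int)
    for l0 in (0, 1):
        for a0 in (0, 1):
            surv = int(y1[l0, a0, 0])
            cells = rng.multinomial(surv - 8, np.full(8, 1 / 8)) + 1
            y2[l0, a0] = cells.reshape(2, 2, 2)
    return CausalTreeCounts.from_arrays(y1, y2)
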