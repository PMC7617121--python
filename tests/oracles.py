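"""Independent brute-force statistical oracles used by the test suite."""

import numpy as np


def brute_kappa(ref, auto):
    """Cohen's kappa by explicit agreement and marginal chance counting."""
    n = len(ref)
    cats = sorted(set(ref) | set(auto))
    p_o = sum(r == a for r, a in zip(ref, auto)) / n
    p_e = sum((list(ref).count(c) / n) * (list(auto).count(c) / n) for c in cats)
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1 - p_e)


def brute_ranks(values):
    """Average ranks with ties, by exhaustive comparison."""
    values = list(values)
    ranks = []
    for v in values:
        less = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        ranks.append(less + (equal + 1) / 2.0)
    return ranks
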