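"""Independent brute-force oracles used by the test suite.

These deliberately re-derive expected values by exhaustive enumeration or
pairwise computation, independent of the library code paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np


def auc_pairwise(scores, labels) -> float:
    """One-vs-rest AUC by exhaustive positive-negative pair counting.

    ``labels`` are booleans (positive class membership); ties count 0.5.
    """
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def two_class_arbitration_accuracy(p_initial: float, p_arbitrator: float) -> float:
    """Closed-form final-label accuracy of the arbitration protocol on a
    two-class problem, by enumeration of the full outcome tree.

    Both initial readers report the truth with probability ``p_initial``;
    both arbitrators with ``p_arbitrator``.  Protocol: concordant initial
    reads stand; else two arbitrators read; concordant arbitrator reads
    stand; else one draw from the average of the arbitrators' rows.
    QC reads never change the label, so they do not enter.
    """
    p, q = p_initial, p_arbitrator
    acc = 0.0
    for o1, o2 in itertools.product((True, False), repeat=2):  # True = correct
        w = (p if o1 else 1 - p) * (p if o2 else 1 - p)
        if o1 == o2:
            acc += w * (1.0 if o1 else 0.0)
            continue
        for a1, a2 in itertools.product((True, False), repeat=2):
            wa = w * (q if a1 else 1 - q) * (q if a2 else 1 - q)
            if a1 == a2:
                acc += wa * (1.0 if a1 else 0.0)
            else:
                acc += wa * q  # consensus: mean row puts mass q on the truth
    return acc


def halving_budget_bound(n_samples: int, rungs, eta: int, budget: int) -> int:
    """Exact epoch total for synchronous successive halving with resume."""
    total = n_samples * rungs[0]
    n = n_samples
    for r_prev, r_next in zip(rungs, rungs[1:]):
        n = max(1, int(np.ceil(n / eta)))
        total += n * (r_next - r_prev)
    n = max(1, int(np.ceil(n / eta)))
    if budget > rungs[-1]:
        total += n * (budget - rungs[-1])
    return total
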