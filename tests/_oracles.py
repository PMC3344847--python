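"""Independent oracles used by the test suite.

Each oracle is a deliberately naive, brute-force computation kept separate
from the library code paths it checks.
"""

from math import comb

import numpy as np


def enumerate_pair_probabilities(seq, model):
    """All nested structures by explicit recursion; Boltzmann-weighted.

    Returns (Z, dense probability matrix).  Exponential in length; only for
    short sequences.
    """
    n = len(seq)

    def wt(i, j):
        return model.weight_of(seq[i], seq[j]) if j - i > model.min_loop else 0.0

    def structs(i, j):
        if i >= j:
            return [(1.0, ())]
        out = list(structs(i + 1, j))
        for k in range(i + model.min_loop + 1, j):
            wk = wt(i, k)
            if wk == 0:
                continue
            for w1, p1 in structs(i + 1, k):
                for w2, p2 in structs(k + 1, j):
                    out.append((wk * w1 * w2, p1 + p2 + ((i, k),)))
        return out

    Z = 0.0
    P = np.zeros((n, n))
    for w, pairs in structs(0, n):
        Z += w
        for (a, b) in pairs:
            P[a, b] += w
    return Z, (P + P.T) / Z


def fisher_two_sided_p(a, b, c, d):
    """Two-sided Fisher p by direct hypergeometric summation.

    Sums, over the support of the margins, every table probability not
    exceeding that of the observed table (with the conventional relative
    tolerance for ties).
    """
    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    denom = comb(n, c1)
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    probs = {k: comb(r1, k) * comb(n - r1, c1 - k) / denom for k in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7))


def scan_uaug(utr5):
    """Position-by-position upstream-AUG scan without find/regex."""
    count = 0
    for i in range(len(utr5) - 2):
        if utr5[i] == "A" and utr5[i + 1] == "T" and utr5[i + 2] == "G":
            count += 1
    return count


def classify_literal(tc, ts):
    """Straight-line transcription of the class rules at default cutoffs:
    inducible (control <= 0, gain >= 1), else resistant (both >= 0.8),
    else sensitive (drop >= 0.8), else unclassified."""
    if tc <= 0.0 and (ts - tc) >= 1.0:
        return "I"
    if tc >= 0.8 and ts >= 0.8:
        return "R"
    if (ts - tc) <= -0.8:
        return "S"
    return "U"
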