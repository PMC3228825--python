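"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths (and libraries) they check.
"""

from math import comb

import numpy as np


def luria_delbruck_counts(m: float, n_cultures: int, rng: np.random.Generator) -> np.ndarray:
    """Sample mutant counts from the continuous Luria-Delbrück model.

    Mutation events per culture are Poisson(m); a mutation arising when
    the (exponentially growing) population has reached a uniformly random
    fraction U of its final size founds a clone of floor(1/U) cells, the
    classic heavy-tailed clone-size law P(size >= k) = 1/k.
    """
    events = rng.poisson(m, size=n_cultures)
    counts = np.zeros(n_cultures)
    for i, k in enumerate(events):
        if k:
            counts[i] = np.floor(1.0 / rng.random(k)).sum()
    return counts


def exact_conditional_two_sided_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided exact conditional p-value for a 2x2 table by enumeration.

    Enumerates every table with the observed margins using integer
    binomial-coefficient weights (the conditional distribution is
    hypergeometric, with weight C(r, x) * C(s, k - x) for x successes in
    the first row) and sums the probabilities of all tables no more
    probable than the observed one.  Integer arithmetic makes tie
    detection exact.
    """
    r, s = a + b, c + d
    n, k = r + s, a + c
    w_obs = comb(r, a) * comb(s, c)
    favorable = 0
    for x in range(max(0, k - s), min(r, k) + 1):
        if comb(r, x) * comb(s, k - x) <= w_obs:
            favorable += comb(r, x) * comb(s, k - x)
    return favorable / comb(n, k)
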