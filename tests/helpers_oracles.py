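"""Independent brute-force oracles used by the test suite only."""

import numpy as np
from scipy.special import gammaln

_LOGFACT = gammaln(np.arange(200) + 1.0)


def fisher_two_sided_oracle(w1, m1, w2, m2):
    """Two-sided Fisher exact p by direct hypergeometric enumeration.

    Sums the probabilities of every 2x2 table with the observed margins whose
    probability does not exceed the observed table's (with a small relative
    tolerance for floating-point ties).  Independent of scipy.stats
    fisher_exact: only the hypergeometric pmf (log-factorials) is used.
    """
    r1, r2 = w1 + m1, w2 + m2
    n = r1 + r2
    if n == 0:
        return None
    c1 = w1 + w2
    ks = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    logpmf = (
        _LOGFACT[c1] - _LOGFACT[ks] - _LOGFACT[c1 - ks]
        + _LOGFACT[n - c1] - _LOGFACT[r1 - ks] - _LOGFACT[n - c1 - r1 + ks]
        - (_LOGFACT[n] - _LOGFACT[r1] - _LOGFACT[n - r1])
    )
    pmf = np.exp(logpmf)
    p_obs = pmf[ks == w1][0]
    return float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())


def bh_stepup_oracle(p_values):
    """Benjamini-Hochberg q-values by the textbook step-up recursion."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / (np.arange(m) + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
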