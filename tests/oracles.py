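"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity by a route disjoint from the package
implementation: exhaustive enumeration with exact rational arithmetic
for the rank-sum and Fisher tests, and a numerical least-squares fit of
the two-coverage model for the ratio estimator.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np
from scipy.optimize import minimize


def wilcoxon_enum_p(values_a, values_b) -> Fraction:
    """Exact two-sided rank-sum p by enumerating every group assignment.

    Requires tie-free data.  Enumerates all C(n, n_a) ways the combined
    ranks could be split, builds the null distribution of the rank sum
    of group a, and doubles the smaller tail (capped at 1).
    """
    a = list(values_a)
    b = list(values_b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in a)
    n, na = len(pooled), len(a)
    total = comb(n, na)
    le = ge = 0
    for combo in itertools.combinations(range(1, n + 1), na):
        w = sum(combo)
        if w <= w_obs:
            le += 1
        if w >= w_obs:
            ge += 1
    p = 2 * min(Fraction(le, total), Fraction(ge, total))
    return min(p, Fraction(1))


def fisher_2xk_enum_p(table) -> Fraction:
    """Exact two-sided Fisher p for a 2xk table, exact rational arithmetic.

    Sums the conditional (multivariate hypergeometric) probabilities of
    all tables with the observed margins whose probability does not
    exceed the observed table's.
    """
    t = [[int(x) for x in row] for row in table]
    row0 = sum(t[0])
    cols = [t[0][j] + t[1][j] for j in range(len(t[0]))]
    n = row0 + sum(t[1])
    denom = comb(n, row0)

    def prob(top: tuple[int, ...]) -> Fraction:
        num = 1
        for c, x in zip(cols, top):
            num *= comb(c, x)
        return Fraction(num, denom)

    p_obs = prob(tuple(t[0]))
    total = Fraction(0)
    ranges = [range(min(row0, c) + 1) for c in cols[:-1]]
    for head in itertools.product(*ranges):
        last = row0 - sum(head)
        if 0 <= last <= cols[-1]:
            p = prob((*head, last))
            if p <= p_obs:
                total += p
    return min(total, Fraction(1))


def lsq_ratio(counts, lengths, k) -> float:
    """Ratio b/a from a brute-force least-squares fit of the
    two-coverage model (grid search then Nelder-Mead refinement).

    Model: expected count of exon i is a*len_i before the variant start
    ordinal k and (a+b)*len_i from k on.
    """
    c = np.asarray(counts, dtype=float)
    lens = np.asarray(lengths, dtype=float)
    pre = slice(0, k - 1)
    post = slice(k - 1, None)

    def sse(params):
        a, b = params
        mu = np.empty_like(c)
        mu[pre] = a * lens[pre]
        mu[post] = (a + b) * lens[post]
        return float(np.sum((c - mu) ** 2))

    a_hint = max(c[pre].sum() / lens[pre].sum(), 1e-9)
    b_hint = max(c[post].sum() / lens[post].sum(), 1e-9)
    scale = max(a_hint, b_hint)
    grid = np.linspace(0, 4 * scale, 81)
    best = min(((sse((ga, gb)), ga, gb) for ga in grid for gb in grid))
    res = minimize(
        sse, x0=[best[1], best[2]], method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-24, "maxiter": 20_000},
    )
    a_hat, b_hat = res.x
    return b_hat / a_hat


def km_by_hand(times, events):
    """Product-limit estimate at each distinct event time, directly from
    the definition S(t) = prod(1 - d_i / n_i)."""
    order = np.argsort(times, kind="stable")
    times = np.asarray(times, dtype=float)[order]
    events = np.asarray(events, dtype=bool)[order]
    out_t, out_s = [], []
    s = 1.0
    for t in np.unique(times[events]):
        n_at_risk = int((times >= t).sum())  # events precede censorings at ties
        d = int(((times == t) & events).sum())
        s *= 1.0 - d / n_at_risk
        out_t.append(float(t))
        out_s.append(s)
    return np.array(out_t), np.array(out_s)
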