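"""Independent reference implementations used to check the package.

These are deliberately naive (explicit loops, exhaustive enumeration) and
share no code with the implementations they validate.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def brute_force_weighted_score(meth_pcts, covs) -> float:
    """Explicit-loop coverage-weighted mean of methylation percentages."""
    total = 0.0
    weight = 0.0
    for m, c in zip(meth_pcts, covs):
        total += m * c
        weight += c
    return total / weight


def mannwhitney_exact(x, y, alternative="two-sided"):
    """Exact Mann-Whitney by enumeration of all rank assignments.

    Assumes no ties.  Returns (U of x vs y, p).  Feasible for n1+n2 <= ~12.
    """
    x, y = list(x), list(y)
    n1, n2 = len(x), len(y)

    def u_of(xs, ys):
        return sum(1 for a in xs for b in ys if a > b)

    u_obs = u_of(x, y)
    pooled = sorted(x + y)
    us = [u_of([pooled[i] for i in idx],
               [pooled[i] for i in range(n1 + n2) if i not in idx])
          for idx in combinations(range(n1 + n2), n1)]
    us = np.array(us)
    if alternative == "two-sided":
        # distribution is symmetric about n1*n2/2
        dev = abs(u_obs - n1 * n2 / 2)
        p = float(np.mean(np.abs(us - n1 * n2 / 2) >= dev))
    elif alternative == "greater":
        p = float(np.mean(us >= u_obs))
    else:
        p = float(np.mean(us <= u_obs))
    return u_obs, p


def pearson_chi2_2xk(table) -> tuple[float, int]:
    """Textbook Pearson statistic for a 2 x k table via explicit loops."""
    table = [list(map(float, row)) for row in table]
    n = sum(sum(row) for row in table)
    row_tot = [sum(row) for row in table]
    col_tot = [sum(table[r][c] for r in range(len(table)))
               for c in range(len(table[0]))]
    chi2 = 0.0
    for r in range(len(table)):
        for c in range(len(table[0])):
            e = row_tot[r] * col_tot[c] / n
            chi2 += (table[r][c] - e) ** 2 / e
    return chi2, (len(table) - 1) * (len(table[0]) - 1)


def welch_t(a, b) -> tuple[float, float]:
    """Closed-form Welch t statistic and Satterthwaite df (no p-value)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
    return float(t), float(df)
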