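"""Independent literal-formula oracles used to verify the statistics engine.

Everything here is written straight from the textbook definitions (sums and
loops, no scipy statistical tests) so the package's implementations are
checked against a genuinely independent route.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.stats import chi2 as _chi2
from scipy.stats import f as _f
from scipy.stats import t as _t


def wilcoxon_exact_enumeration(a, b) -> float:
    """Two-sided exact rank-sum p by full enumeration of group assignments.

    Enumerates every way the pooled ranks can be split between the groups and
    uses the symmetric convention p = min(1, 2*min(P(U <= u), P(U >= u))).
    Tie-free inputs only.
    """
    a, b = list(a), list(b)
    n1, n2 = len(a), len(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(rank[v] for v in a) - n1 * (n1 + 1) / 2
    le = ge = total = 0
    for combo in itertools.combinations(range(1, n1 + n2 + 1), n1):
        u = sum(combo) - n1 * (n1 + 1) / 2
        total += 1
        if u <= u_obs:
            le += 1
        if u >= u_obs:
            ge += 1
    return min(1.0, 2.0 * min(le, ge) / total)


def student_t_formula(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = len(a), len(b)
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    df = n1 + n2 - 2
    return t, 2 * _t.sf(abs(t), df)


def welch_t_formula(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    v1, v2 = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (len(a) - 1) + v2**2 / (len(b) - 1))
    return t, 2 * _t.sf(abs(t), df)


def oneway_f_formula(groups):
    groups = [np.asarray(g, float) for g in groups]
    k = len(groups)
    n = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    f = (ss_between / (k - 1)) / (ss_within / (n - k))
    return f, _f.sf(f, k - 1, n - k)


def welch_anova_formula(groups):
    groups = [np.asarray(g, float) for g in groups]
    k = len(groups)
    n = np.array([len(g) for g in groups], float)
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])
    w = n / v
    mw = (w * m).sum() / w.sum()
    tmp = (((1 - w / w.sum()) ** 2) / (n - 1)).sum() / (k**2 - 1)
    f = ((w * (m - mw) ** 2).sum() / (k - 1)) / (1 + 2 * (k - 2) * tmp)
    return f, _f.sf(f, k - 1, 1.0 / (3.0 * tmp))


def levene_median_formula(groups):
    """Brown–Forsythe: one-way F on |x - group median|."""
    z = [np.abs(np.asarray(g, float) - np.median(g)) for g in groups]
    return oneway_f_formula(z)


def kruskal_formula(groups):
    """Tie-corrected Kruskal–Wallis H with chi-square p."""
    groups = [np.asarray(g, float) for g in groups]
    pooled = np.concatenate(groups)
    n = len(pooled)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(n)
    sorted_vals = pooled[order]
    i = 0
    pos = 1.0
    while i < n:
        j = i
        while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        avg = (pos + pos + (j - i)) / 2.0
        for kk in range(i, j + 1):
            ranks[order[kk]] = avg
        pos += j - i + 1
        i = j + 1
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    h /= correction
    return h, _chi2.sf(h, len(groups) - 1)


# --- multiple-testing adjustments, step by step ----------------------------


def bonferroni_adjust(p):
    m = len(p)
    return [min(1.0, x * m) for x in p]


def holm_adjust(p):
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    out = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[idx]))
        out[idx] = running
    return out


def hochberg_adjust(p):
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    out = [0.0] * m
    running = 1.0
    for rank in range(m - 1, -1, -1):
        idx = order[rank]
        running = min(running, min(1.0, (m - rank) * p[idx]))
        out[idx] = running
    return out


def bh_adjust(p):
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    out = [0.0] * m
    running = 1.0
    for rank in range(m - 1, -1, -1):
        idx = order[rank]
        running = min(running, min(1.0, m / (rank + 1) * p[idx]))
        out[idx] = running
    return out


def by_adjust(p):
    m = len(p)
    c = sum(1.0 / i for i in range(1, m + 1))
    order = sorted(range(m), key=lambda i: p[i])
    out = [0.0] * m
    running = 1.0
    for rank in range(m - 1, -1, -1):
        idx = order[rank]
        running = min(running, min(1.0, c * m / (rank + 1) * p[idx]))
        out[idx] = running
    return out
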