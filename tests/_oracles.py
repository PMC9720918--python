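"""Independent brute-force oracles used to check the library implementations.

Everything here is written as directly as possible from first principles
(window enumeration, full permutation enumeration, hand product-limit
computation) and deliberately shares no code with the package.
"""
from __future__ import annotations

import itertools

import numpy as np


def load_bruteforce(reads: list[tuple[str, int]], exponent: float = 3.0,
                    kind: str = "MHL") -> float:
    """Window-enumeration haplotype load on aligned in-block call strings.

    ``reads`` are (calls, count) with calls of block length over '0','1','?'.
    Returns NaN when no window of any length is evaluable.
    """
    if not reads:
        return float("nan")
    l = len(reads[0][0])
    target_char = "1" if kind == "MHL" else "0"
    num = [0.0] * (l + 1)
    den = [0.0] * (l + 1)
    for s, c in reads:
        assert len(s) == l
        for i in range(1, l + 1):
            for j in range(l - i + 1):
                w = s[j: j + i]
                if "?" in w:
                    continue
                den[i] += c
                if w == target_char * i:
                    num[i] += c
    w_sum = 0.0
    acc = 0.0
    for i in range(1, l + 1):
        if den[i] > 0:
            wi = i ** exponent
            w_sum += wi
            acc += wi * num[i] / den[i]
    return acc / w_sum if w_sum > 0 else float("nan")


def r2_bruteforce(pair_counts: dict[tuple[int, int], int]) -> float | None:
    """r^2 via Pearson correlation on the expanded two-column call list."""
    left, right = [], []
    for (a, b), c in pair_counts.items():
        left.extend([a] * c)
        right.extend([b] * c)
    if not left:
        return None
    la, ra = np.asarray(left, float), np.asarray(right, float)
    if la.std() == 0 or ra.std() == 0:
        return None
    r = np.corrcoef(la, ra)[0, 1]
    return float(r * r)


def maximal_runs(linked: list[bool]) -> list[tuple[int, int]]:
    """Exhaustive scan for maximal runs of sites joined by linked pairs.

    ``linked[k]`` says whether sites k and k+1 are linked; returns inclusive
    (first_site, last_site) tuples with at least two sites.
    """
    runs = []
    k = 0
    while k < len(linked):
        if linked[k]:
            j = k
            while j < len(linked) and linked[j]:
                j += 1
            runs.append((k, j))
            k = j
        else:
            k += 1
    return runs


def _u_statistic(case: np.ndarray, control: np.ndarray) -> float:
    u = 0.0
    for x in case:
        for y in control:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def ranksum_exact_p(case, control, alternative: str) -> float:
    """One-sided rank-sum p by enumerating every group assignment."""
    case = np.asarray(case, float)
    control = np.asarray(control, float)
    pooled = np.concatenate([case, control])
    n = case.size
    obs = _u_statistic(case, control)
    total = 0
    hits = 0
    for idx in itertools.combinations(range(pooled.size), n):
        mask = np.zeros(pooled.size, bool)
        mask[list(idx)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        total += 1
        if alternative == "greater":
            hits += u >= obs - 1e-12
        elif alternative == "less":
            hits += u <= obs + 1e-12
        else:
            raise ValueError(alternative)
    return hits / total


def signrank_exact_p(diffs, alternative: str) -> float:
    """One-sided signed-rank p by enumerating all 2^n sign assignments."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = _midranks(np.abs(d))
    obs = ranks[d > 0].sum()
    n = d.size
    total = 0
    hits = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        total += 1
        if alternative == "greater":
            hits += w >= obs - 1e-12
        elif alternative == "less":
            hits += w <= obs + 1e-12
        else:
            raise ValueError(alternative)
    return hits / total


def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="stable")
    ranks = np.empty(values.size, float)
    i = 0
    sorted_vals = values[order]
    while i < values.size:
        j = i
        while j < values.size and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    return ranks


def bh_stepup(p_values) -> np.ndarray:
    """Benjamini-Hochberg q-values straight from the step-up definition."""
    p = np.asarray(p_values, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m, float)
    running_min = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, m * p[idx] / rank)
        q[idx] = running_min
    return q


def auc_paircount(scores, labels) -> float:
    """AUC by exhaustive positive/negative pair counting (ties count 1/2)."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    pos = s[y]
    neg = s[~y]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (pos.size * neg.size)


def km_product_limit(times, events) -> list[tuple[float, float]]:
    """(event time, survival) pairs from a hand risk-set recomputation."""
    t = np.asarray(times, float)
    e = np.asarray(events, bool)
    out = []
    s = 1.0
    for ti in sorted(set(t[e])):
        at_risk = int((t >= ti).sum())
        d = int(((t == ti) & e).sum())
        s *= 1.0 - d / at_risk
        out.append((ti, s))
    return out


def logrank_manual(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank chi-square from the O-E / hypergeometric-V tables."""
    from scipy.stats import chi2

    t = np.asarray(times, float)
    e = np.asarray(events, bool)
    g = np.asarray(groups)
    labels = sorted(set(g))
    assert len(labels) == 2
    a = g == labels[0]
    o_minus_e = 0.0
    var = 0.0
    for ti in sorted(set(t[e])):
        n = int((t >= ti).sum())
        n1 = int((t >= ti)[a].sum())
        d = int(((t == ti) & e).sum())
        d1 = int(((t == ti) & e & a).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    stat = o_minus_e ** 2 / var
    return stat, float(chi2.sf(stat, 1))
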