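"""Independent brute-force oracles used by the test suite.

These deliberately re-derive each quantity from first principles (plain
loops, textbook formulas) so that agreement with the package is a
two-route check, not a tautology.
"""

import numpy as np


def product_limit(times, deltas):
    """Kaplan-Meier by direct product over distinct event times."""
    times = np.asarray(times, dtype=float)
    deltas = np.asarray(deltas, dtype=int)
    out_t, out_s = [], []
    s = 1.0
    for t in np.unique(times[deltas == 1]):
        at_risk = int((times >= t).sum())
        d = int(((times == t) & (deltas == 1)).sum())
        s *= 1.0 - d / at_risk
        out_t.append(t)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)


def km_median(times, deltas):
    t, s = product_limit(times, deltas)
    below = np.nonzero(s <= 0.5 + 1e-9)[0]
    return float(t[below[0]]) if len(below) else np.inf


def logrank_chi2(times, deltas, labels):
    """k-sample log-rank statistic from the textbook O-E / covariance form."""
    times = np.asarray(times, dtype=float)
    deltas = np.asarray(deltas, dtype=int)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    g = len(groups)
    OmE = np.zeros(g)
    V = np.zeros((g, g))
    for t in np.unique(times[deltas == 1]):
        at_risk = times >= t
        n_t = int(at_risk.sum())
        d_t = int(((times == t) & (deltas == 1)).sum())
        n_gt = np.array([(at_risk & (labels == gr)).sum() for gr in groups], dtype=float)
        d_gt = np.array(
            [((times == t) & (deltas == 1) & (labels == gr)).sum() for gr in groups],
            dtype=float,
        )
        OmE += d_gt - d_t * n_gt / n_t
        if n_t > 1:
            frac = n_gt / n_t
            c = d_t * (n_t - d_t) / (n_t - 1)
            V += c * (np.diag(frac) - np.outer(frac, frac))
    sub = slice(0, g - 1)
    stat = float(OmE[sub] @ np.linalg.solve(V[sub, sub], OmE[sub]))
    return stat


def mannwhitney_z_p(a, b):
    """Tie-corrected normal-approximation Mann-Whitney with continuity
    correction (two-sided), from the textbook formulas."""
    from scipy.stats import rankdata, norm

    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    ranks = rankdata(np.concatenate([a, b]))
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = (counts**3 - counts).sum() / (n * (n - 1))
    sigma = np.sqrt(n1 * n2 / 12.0 * (n + 1 - tie_term))
    num = u1 - mu
    num -= np.sign(num) * 0.5  # continuity correction
    z = num / sigma
    p = 2 * norm.sf(abs(z))
    return u1, min(p, 1.0)


def anova_f_p(values, labels):
    """One-way ANOVA from raw sums of squares, plus the F tail."""
    from scipy.stats import f as fdist

    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in np.unique(labels)]
    k = len(groups) - 1
    n = len(values)
    grand = values.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    F = (ssb / k) / (ssw / (n - k - 1))
    return F, float(fdist.sf(F, k, n - k - 1))
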