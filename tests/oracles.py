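"""Independent brute-force reference implementations used to cross-check
the package's statistics.  Deliberately written from the textbook formulas
(explicit sums, scipy.special distribution functions only), independent of
the code paths they validate."""

import math

import numpy as np
from scipy import special


def t_sf(t, df):
    """Upper tail P(T > t) of Student's t via the regularized beta function."""
    return 1.0 - special.stdtr(df, t)


def one_sample_t_oracle(values, popmean):
    """(t, p_two_sided, p_greater, p_less) computed from explicit sums."""
    values = list(map(float, values))
    n = len(values)
    mean = sum(values) / n
    ss = sum((v - mean) ** 2 for v in values)
    sd = math.sqrt(ss / (n - 1))
    if sd == 0:
        if mean == popmean:
            return 0.0, 1.0, 1.0, 1.0
        t = math.inf if mean > popmean else -math.inf
        return t, 0.0, (0.0 if t > 0 else 1.0), (0.0 if t < 0 else 1.0)
    t = (mean - popmean) / (sd / math.sqrt(n))
    df = n - 1
    p_greater = t_sf(t, df)
    p_less = special.stdtr(df, t)
    p_two = 2.0 * t_sf(abs(t), df)
    return t, min(p_two, 1.0), p_greater, p_less


def paired_t_oracle(x, y):
    """(t, p_two_sided) of the paired t-test on matched samples."""
    diffs = [float(b) - float(a) for a, b in zip(x, y)]
    return one_sample_t_oracle(diffs, 0.0)[:2]


def brown_forsythe_oracle(*groups):
    """(F, p) of Levene's test with median centering, from the anova formula."""
    z = [[abs(v - float(np.median(g))) for v in g] for g in groups]
    k = len(z)
    n_total = sum(len(g) for g in z)
    grand = sum(sum(g) for g in z) / n_total
    group_means = [sum(g) / len(g) for g in z]
    ss_between = sum(len(g) * (gm - grand) ** 2 for g, gm in zip(z, group_means))
    ss_within = sum(sum((v - gm) ** 2 for v in g) for g, gm in zip(z, group_means))
    df1, df2 = k - 1, n_total - k
    stat = (ss_between / df1) / (ss_within / df2)
    p = special.fdtrc(df1, df2, stat)
    return stat, p


def confusion_oracle(seeded, detected, universe):
    """Element-by-element classification into tp/fp/tn/fn."""
    tp, fp, tn, fn = set(), set(), set(), set()
    for pid in universe:
        positive = pid in seeded
        called = pid in detected
        if positive and called:
            tp.add(pid)
        elif positive:
            fn.add(pid)
        elif called:
            fp.add(pid)
        else:
            tn.add(pid)
    return tp, fp, tn, fn


def measures_oracle(tp, fp, tn, fn):
    """(specificity, sensitivity, precision, accuracy) by direct counting."""
    tp, fp, tn, fn = len(tp), len(fp), len(tn), len(fn)
    specificity = tn / (tn + fp) if tn + fp else 1.0
    sensitivity = tp / (tp + fn) if tp + fn else 1.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    accuracy = (tp + tn) / (tp + tn + fp + fn)
    return specificity, sensitivity, precision, accuracy
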