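"""Independent reference implementations used to cross-check the package.

Everything here is written as literal, loop-based transcriptions of the
definitions, deliberately sharing no code with hemifc.
"""

import math

import numpy as np


def bh_fdr_brute(pvals):
    """Literal BH step-up: sort, find largest i with p(i) <= i*q/m by scanning
    candidate q levels; q-value of a test = smallest q at which it is rejected."""
    p = list(pvals)
    m = len(p)
    srt = sorted(p)
    qvals = []
    for target in p:
        # q-value = smallest level at which the step-up rule rejects `target`,
        # i.e. min over j with p(j) >= target of p(j) * m / j
        cands = [srt[j - 1] * m / j for j in range(1, m + 1)
                 if srt[j - 1] >= target]
        qvals.append(min(min(cands), 1.0))
    return qvals


def hemispheric_fc_brute(r, z, roi_order, hemisphere_of, roi, threshold,
                         mode, weight):
    """Literal loop over all target ROIs."""
    i = roi_order.index(roi)
    rfc = lfc = 0.0
    n_r = n_l = 0
    for j, target in enumerate(roi_order):
        if j == i:
            continue
        hemi = hemisphere_of(target)
        if hemi not in ("L", "R"):
            continue
        rij = r[i][j]
        if mode == "signed":
            supra = rij > threshold
        else:
            supra = abs(rij) > threshold
        if not supra:
            continue
        w = abs(z[i][j]) if weight == "z" else abs(rij)
        if hemi == "R":
            rfc += w
            n_r += 1
        else:
            lfc += w
            n_l += 1
    return rfc, lfc, n_r, n_l


def paired_t_brute(x, y):
    d = [a - b for a, b in zip(x, y)]
    n = len(d)
    mean = sum(d) / n
    var = sum((v - mean) ** 2 for v in d) / (n - 1)
    t = mean / math.sqrt(var / n)
    return t, n - 1


def anova_brute(groups):
    allv = [v for g in groups for v in g]
    grand = sum(allv) / len(allv)
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum(sum((v - sum(g) / len(g)) ** 2 for v in g) for g in groups)
    df_b = len(groups) - 1
    df_w = len(allv) - len(groups)
    return (ssb / df_b) / (ssw / df_w), df_b, df_w


def pearson_brute(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def mann_whitney_u_brute(x, y):
    """Enumerate all pairings: U = #(x > y) + 0.5 #(x == y)."""
    u = 0.0
    for a in x:
        for b in y:
            if a > b:
                u += 1.0
            elif a == b:
                u += 0.5
    return u


def two_sample_t_brute(a, b):
    n1, n2 = len(a), len(b)
    m1, m2 = sum(a) / n1, sum(b) / n2
    v1 = sum((v - m1) ** 2 for v in a) / (n1 - 1)
    v2 = sum((v - m2) ** 2 for v in b) / (n2 - 1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    t = (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    return t, n1 + n2 - 2


def bh_reject_brute(pvals, q):
    """Step-up rejection set: sort, largest i with p(i) <= i*q/m."""
    srt = sorted(enumerate(pvals), key=lambda kv: kv[1])
    m = len(pvals)
    k = 0
    for i, (_, p) in enumerate(srt, start=1):
        if p <= i * q / m:
            k = i
    rejected = {idx for idx, _ in srt[:k]}
    return [i in rejected for i in range(m)]
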