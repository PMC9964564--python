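"""Naive, loop-based reference implementations used as independent oracles.

These are deliberately written as direct transcriptions of the metric
definitions — explicit Python loops, no vectorisation, no shared code
with the package — so agreement with the package is meaningful.
"""

import math

import numpy as np


def naive_resultant_distance(coords):
    """Per-sample Euclidean norm of the mean-centred coordinate rows."""
    coords = np.asarray(coords, dtype=float)
    means = [sum(coords[:, j]) / len(coords) for j in range(3)]
    out = []
    for row in coords:
        out.append(math.sqrt(sum((row[j] - means[j]) ** 2 for j in range(3))))
    return np.array(out)


def naive_fuzzy_entropy(x, m=2, r_factor=0.2, gradient=2):
    """Quadruple-loop fuzzy entropy (Chen-style) for short series.

    Distances are taken on the SD-standardised series with tolerance
    r_factor, mirroring the relative-tolerance convention."""
    x = np.asarray(x, dtype=float)
    sd = np.std(x, ddof=1)
    x = x / sd
    n = len(x)
    r = r_factor

    def phi(dim):
        count = n - dim
        templates = []
        for i in range(count):
            seg = x[i : i + dim]
            mean = sum(seg) / dim
            templates.append([v - mean for v in seg])
        total = 0.0
        for i in range(count):
            acc = 0.0
            for j in range(count):
                if i == j:
                    continue
                d = 0.0
                for k in range(dim):
                    d = max(d, abs(templates[i][k] - templates[j][k]))
                acc += math.exp(-(d**gradient) / r)
            total += acc / (count - 1)
        return total / count

    return math.log(phi(m)) - math.log(phi(m + 1))


def naive_dfa_fluctuation(x, box, order=1):
    """Loop-based DFA fluctuation at one window size."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    mean = sum(x) / n
    profile = []
    acc = 0.0
    for v in x:
        acc += v - mean
        profile.append(acc)
    n_boxes = n // box
    sq_sum = 0.0
    count = 0
    t = np.arange(box, dtype=float)
    for b in range(n_boxes):
        seg = np.array(profile[b * box : (b + 1) * box])
        coef = np.polyfit(t, seg, order)
        trend = np.polyval(coef, t)
        for resid in seg - trend:
            sq_sum += resid**2
            count += 1
    return math.sqrt(sq_sum / count)


def naive_two_pass_sd(x):
    """Two-pass sample standard deviation."""
    x = np.asarray(x, dtype=float)
    mean = sum(x) / len(x)
    return math.sqrt(sum((v - mean) ** 2 for v in x) / (len(x) - 1))


def naive_rm_anova_ss(values):
    """Sum-of-squares of a two-way (subject, condition) fixed-effects fit,
    computed cell by cell."""
    values = np.asarray(values, dtype=float)
    s, k = values.shape
    grand = values.sum() / values.size
    ss_subj = 0.0
    for i in range(s):
        ss_subj += k * (values[i].sum() / k - grand) ** 2
    ss_cond = 0.0
    for j in range(k):
        ss_cond += s * (values[:, j].sum() / s - grand) ** 2
    ss_err = 0.0
    for i in range(s):
        for j in range(k):
            fitted = values[i].sum() / k + values[:, j].sum() / s - grand
            ss_err += (values[i, j] - fitted) ** 2
    return ss_subj, ss_cond, ss_err
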