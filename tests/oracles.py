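"""Brute-force reference implementations used only by the tests.

Everything here is written with explicit loops straight from the defining
formulas, independent of numpy/scipy code paths in the package, so that the
package's descriptors can be checked against first principles on small
samples.
"""

import math


def mean(xs):
    return sum(xs) / len(xs)


def central_moment(xs, j):
    m = mean(xs)
    return sum((x - m) ** j for x in xs) / len(xs)


def skewness(xs):
    m2 = central_moment(xs, 2)
    return central_moment(xs, 3) / m2**1.5


def kurtosis(xs):
    m2 = central_moment(xs, 2)
    return central_moment(xs, 4) / m2**2


def quantile(xs, p):
    """Linear interpolation of order statistics, h = (n - 1) p + 1."""
    s = sorted(xs)
    h = (len(s) - 1) * p + 1
    lo = math.floor(h)
    frac = h - lo
    if lo >= len(s):
        return s[-1]
    return s[lo - 1] + frac * (s[lo] - s[lo - 1])


def median(xs):
    return quantile(xs, 0.5)


def interdecile_range(xs):
    return quantile(xs, 0.9) - quantile(xs, 0.1)


def pearson_r(xs, ys):
    mx, my = mean(xs), mean(ys)
    num = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    den = math.sqrt(sum((x - mx) ** 2 for x in xs) * sum((y - my) ** 2 for y in ys))
    return num / den


def nested_subsample_r(between_sd, within_sd, k_full, k_reduced):
    """Population correlation of full-sample and nested-subsample means."""
    cov = between_sd**2 + within_sd**2 / k_full
    var_full = between_sd**2 + within_sd**2 / k_full
    var_reduced = between_sd**2 + within_sd**2 / k_reduced
    return cov / math.sqrt(var_full * var_reduced)
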