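"""Independent brute-force reimplementations of the segment statistics.

Naive pure-Python loops straight from the definitions, used only to check
the vectorized extractor.
"""

import math


def naive_mean(x):
    return sum(x) / len(x)


def naive_sum(x):
    return sum(x)


def naive_sd(x):
    m = naive_mean(x)
    return math.sqrt(sum((v - m) ** 2 for v in x) / (len(x) - 1))


def naive_variance(x):
    return naive_sd(x) ** 2


def naive_mad(x):
    m = naive_mean(x)
    return sum(abs(v - m) for v in x) / len(x)


def naive_sem(x):
    return naive_sd(x) / math.sqrt(len(x))


def naive_skewness(x):
    m = naive_mean(x)
    s = naive_sd(x)
    if s == 0:
        return 0.0
    return (sum((v - m) ** 3 for v in x) / len(x)) / s**3


def naive_kurtosis(x):
    m = naive_mean(x)
    s = naive_sd(x)
    if s == 0:
        return 0.0
    return (sum((v - m) ** 4 for v in x) / len(x)) / s**4


def naive_quantile(x, p):
    """Value at position p*(n+1) among the order statistics, clamped."""
    s = sorted(x)
    n = len(s)
    h = p * (n + 1)
    if h <= 1:
        return s[0]
    if h >= n:
        return s[-1]
    lo = math.floor(h)
    return s[lo - 1] + (h - lo) * (s[lo] - s[lo - 1])


def naive_unique(x):
    return float(len(set(x)))


def naive_feature_dict(x):
    x = list(x)
    out = {
        "mean": naive_mean(x),
        "sum": naive_sum(x),
        "max": max(x),
        "min": min(x),
        "median": naive_quantile(x, 0.5),
        "sd": naive_sd(x),
        "kurtosis": naive_kurtosis(x),
        "mad": naive_mad(x),
        "sem": naive_sem(x),
        "skewness": naive_skewness(x),
        "variance": naive_variance(x),
        "unique": naive_unique(x),
    }
    for pct in (10, 20, 25, 30, 40, 50, 60, 70, 75, 80, 90):
        out[f"quantile{pct}"] = naive_quantile(x, pct / 100)
    return out
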