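"""Independent brute-force oracles used only by the tests.

Deliberately naive: explicit sort-based average ranking and textbook
summation formulas, sharing no code path with the package.
"""

import math


def average_ranks(values):
    """Average ranks (1-based) with ties sharing the mean of their
    positions, computed by explicit sorting."""
    n = len(values)
    order = sorted(range(n), key=lambda idx: values[idx])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1  # mean of 1-based positions i+1 .. j+1
        for kk in range(i, j + 1):
            ranks[order[kk]] = avg
        i = j + 1
    return ranks


def pearson(x, y):
    """Textbook product-moment correlation via explicit sums."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def spearman(x, y):
    """Rank then product-moment on the ranks."""
    return pearson(average_ranks(x), average_ranks(y))


def sample_variance(values):
    """Unbiased (n-1) sample variance by direct summation."""
    n = len(values)
    mean = sum(values) / n
    return sum((v - mean) ** 2 for v in values) / (n - 1)
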