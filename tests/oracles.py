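"""Independent brute-force oracles used to cross-check the implementation."""

import numpy as np


def anova_icc_bruteforce(y, form):
    """ICC by two-way ANOVA with sums of squares from direct summation.

    Deliberately written with explicit loops, independent of the
    vectorized implementation it checks.
    """
    y = np.asarray(y, float)
    n, k = y.shape
    grand = sum(y[i][j] for i in range(n) for j in range(k)) / (n * k)
    row_means = [sum(y[i]) / k for i in range(n)]
    col_means = [sum(y[:, j]) / n for j in range(k)]
    ssr = k * sum((rm - grand) ** 2 for rm in row_means)
    ssc = n * sum((cm - grand) ** 2 for cm in col_means)
    sst = sum((y[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if form == "A1":
        return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
    if form == "C1":
        return (msr - mse) / (msr + (k - 1) * mse)
    raise ValueError(form)
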