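"""Independent brute-force oracles, coded with explicit loops.

These deliberately avoid the package's vectorized code paths: standard
deviations are accumulated by hand, pairs are visited with double loops,
and the NormFinder moments estimator is written directly from the model
description.  They exist to cross-check the implementation, never to
replace it.
"""

import math


def sample_sd(values):
    n = len(values)
    mean = sum(values) / n
    return math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))


def genorm_m_brute(q):
    """Mean pairwise variation per gene via a direct double loop."""
    n_genes = len(q)
    n_samples = len(q[0])
    m = []
    for j in range(n_genes):
        total = 0.0
        for k in range(n_genes):
            if k == j:
                continue
            ratios = [math.log2(q[j][s] / q[k][s]) for s in range(n_samples)]
            total += sample_sd(ratios)
        m.append(total / (n_genes - 1))
    return m


def genorm_v_curve_brute(q, order):
    """V(n, n+1) from the definition: geometric-mean NFs, then sd of log2 ratio."""
    n_genes = len(order)
    n_samples = len(q[0])

    def nf(top_n, s):
        prod = 1.0
        for j in order[:top_n]:
            prod *= q[j][s]
        return prod ** (1.0 / top_n)

    out = []
    for n in range(2, n_genes):
        ratios = [math.log2(nf(n, s) / nf(n + 1, s)) for s in range(n_samples)]
        out.append(sample_sd(ratios))
    return out


def normfinder_brute(ct, group_labels):
    """Method-of-moments stability values, explicit loops throughout.

    ``ct`` is a genes x samples nested list; ``group_labels`` one label
    per sample.  Steps: sample-center log2 expression (y = -Ct) across
    genes; per gene/group means and variances; correct variances for the
    centering covariance and floor at 0; row-center the group means;
    moment-estimate the inter-group variance; shrink; combine.
    """
    k = len(ct)
    n_samples = len(ct[0])
    groups = []
    for g in group_labels:
        if g not in groups:
            groups.append(g)
    n_groups = len(groups)

    y = [[-ct[i][s] for s in range(n_samples)] for i in range(k)]
    for s in range(n_samples):
        col_mean = sum(y[i][s] for i in range(k)) / k
        for i in range(k):
            y[i][s] -= col_mean

    d = [[0.0] * n_groups for _ in range(k)]
    var = [[0.0] * n_groups for _ in range(k)]
    sizes = []
    for gi, g in enumerate(groups):
        idx = [s for s in range(n_samples) if group_labels[s] == g]
        n_g = len(idx)
        sizes.append(n_g)
        s2 = []
        for i in range(k):
            vals = [y[i][s] for s in idx]
            mean = sum(vals) / n_g
            d[i][gi] = mean
            s2.append(sum((v - mean) ** 2 for v in vals) / (n_g - 1))
        t_hat = sum(s2) * k / (k - 1)
        for i in range(k):
            var[i][gi] = max((s2[i] - t_hat / k**2) * k / (k - 2), 0.0)

    for i in range(k):
        row_mean = sum(d[i]) / n_groups
        for gi in range(n_groups):
            d[i][gi] -= row_mean

    samp = [[var[i][gi] / sizes[gi] for gi in range(n_groups)] for i in range(k)]
    if n_groups == 1:
        return [math.sqrt(var[i][0]) for i in range(k)]

    sum_d2 = sum(d[i][gi] ** 2 for i in range(k) for gi in range(n_groups))
    mean_samp = sum(samp[i][gi] for i in range(k) for gi in range(n_groups)) / (k * n_groups)
    gamma2 = max(0.0, sum_d2 / ((k - 1) * (n_groups - 1)) - mean_samp)

    stability = []
    for i in range(k):
        acc = 0.0
        for gi in range(n_groups):
            denom = gamma2 + samp[i][gi]
            d_shrunk = d[i][gi] * (gamma2 / denom) if denom > 0 else 0.0
            acc += abs(d_shrunk) + math.sqrt(samp[i][gi])
        stability.append(acc / n_groups)
    return stability
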