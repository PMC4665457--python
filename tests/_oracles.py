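"""Shared independent oracles: plug-in arithmetic on raw counts."""

import numpy as np


def plugin_parameters(table, zero_fix="error"):
    """Posterior-mean plug-in (phi, theta, marginals) from raw counts.

    phi = s/(s+r) per cell, theta = m/m.., marginals from aggregated counts —
    straight count arithmetic, independent of the samplers.
    """
    s = table.s.astype(float).copy()
    r = table.r.astype(float).copy()
    if zero_fix == "add_one":
        s[s == 0] = 1.0
        r[r == 0] = 1.0
    m = table.m.astype(float)
    phi = s / (s + r)
    theta = m / m.sum()
    marg1 = s.sum(axis=1) / (s.sum(axis=1) + r.sum(axis=1))
    marg2 = s.sum(axis=0) / (s.sum(axis=0) + r.sum(axis=0))
    return phi, theta, marg1, marg2


def brute_force_auc(p_diseased, p_nondiseased):
    """Tie-corrected AUC by explicit double loop over category pairs."""
    p = np.asarray(p_diseased, float)
    q = np.asarray(p_nondiseased, float)
    p, q = p / p.sum(), q / q.sum()
    total = 0.0
    for i in range(p.size):
        for j in range(q.size):
            if i > j:
                total += p[i] * q[j]
            elif i == j:
                total += 0.5 * p[i] * q[j]
    return total
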