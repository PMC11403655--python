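"""Independent brute-force oracles used only by the tests.

The naive WHAM solver below is deliberately written with plain Python
loops and no shared code with the production solver, so the two can serve
as independent cross-checks of the same fixed point.
"""

from __future__ import annotations

import math

from pmfkit.constants import KB


def naive_wham(counts, centers, window_centers, window_ks, temperature,
               tol=1e-10, max_iter=200_000):
    """Plain fixed-point WHAM on nested Python lists.

    counts: n_windows x n_bins histogram counts; centers: bin centers.
    Returns (p_per_bin, f_i_kJ_mol) with f_0 = 0 and p normalized over
    occupied bins.
    """
    n_win = len(counts)
    n_bins = len(centers)
    beta = 1.0 / (KB * temperature)
    n_i = [sum(row) for row in counts]
    total = [sum(counts[i][b] for i in range(n_win)) for b in range(n_bins)]
    bias = [
        [0.5 * window_ks[i] * (centers[b] - window_centers[i]) ** 2
         for b in range(n_bins)]
        for i in range(n_win)
    ]
    f = [0.0] * n_win
    for _ in range(max_iter):
        p = []
        for b in range(n_bins):
            if total[b] == 0:
                p.append(0.0)
                continue
            denom = sum(
                n_i[i] * math.exp(beta * (f[i] - bias[i][b]))
                for i in range(n_win)
            )
            p.append(total[b] / denom)
        norm = sum(p)
        p = [x / norm for x in p]
        f_new = []
        for i in range(n_win):
            z = sum(p[b] * math.exp(-beta * bias[i][b]) for b in range(n_bins))
            f_new.append(-math.log(z) / beta)
        f_new = [x - f_new[0] for x in f_new]
        delta = max(abs(a - b) for a, b in zip(f_new, f))
        f = f_new
        if delta < tol:
            break
    return p, f
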