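"""Independent brute-force oracles used to check the fast implementations.

These deliberately take different computational routes from the package:
the BH oracle is the literal quadratic step-up definition, the KS oracle an
O(n) walk over every rank of the profile, and the GSEA oracle the literal
running sum over the whole ranked list.
"""
from __future__ import annotations

import numpy as np


def bh_stepup_oracle(pvalues):
    """Literal Benjamini–Hochberg step-up, O(m^2)."""
    p = list(map(float, pvalues))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [None] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        candidate = min(1.0, p[i] * m / rank_from_top)
        running_min = min(running_min, candidate)
        adjusted[i] = running_min
    return np.array(adjusted)


def ks_walk_oracle(hit_positions, n):
    """KS enrichment by walking every rank 1..n of the profile.

    ``hit_positions`` are the 1-based ranks of the tags. Tracks the two
    one-sided deviations of the hit ECDF from the uniform and returns the
    signed larger one (ties to the positive branch).
    """
    hits = set(int(h) for h in hit_positions)
    t = len(hits)
    a = -np.inf
    b = -np.inf
    seen = 0
    for j in range(1, n + 1):
        b = max(b, j / n - seen / t)
        if j in hits:
            seen += 1
            a = max(a, seen / t - j / n)
    return a if a >= b else -b


def gsea_running_sum_oracle(metrics, is_hit):
    """Literal weighted running sum (exponent 1) over the full ranked list.

    ``metrics`` are the ranking metric values in list order; ``is_hit``
    marks set membership per position. Returns the signed maximum
    deviation from zero (ties to the positive branch).
    """
    metrics = np.asarray(metrics, dtype=float)
    is_hit = np.asarray(is_hit, dtype=bool)
    n = len(metrics)
    n_hits = int(is_hit.sum())
    if n_hits == n:
        return 1.0
    w_total = np.abs(metrics[is_hit]).sum()
    running = 0.0
    best = 0.0
    for j in range(n):
        if is_hit[j]:
            if w_total > 0:
                running += abs(metrics[j]) / w_total
            else:
                running += 1.0 / n_hits
        else:
            running -= 1.0 / (n - n_hits)
        if abs(running) > abs(best) or (abs(running) == abs(best) and running > best):
            best = running
    return best
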