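"""Independent brute-force reference implementations used by the tests.

These deliberately avoid the package's vectorized code paths: plain
Python loops over gene pairs and textbook formulas only.
"""

import math


def pearson(x, y):
    """Textbook Pearson correlation: cov / (sigma_x * sigma_y)."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / (n - 1)
    sx = math.sqrt(sum((a - mx) ** 2 for a in x) / (n - 1))
    sy = math.sqrt(sum((b - my) ** 2 for b in y) / (n - 1))
    if sx == 0 or sy == 0:
        return 0.0
    return cov / (sx * sy)


def sample_sd(x):
    n = len(x)
    m = sum(x) / n
    return math.sqrt(sum((a - m) ** 2 for a in x) / (n - 1))


def ci_brute_force(member_rows, nonmember_rows, eps_pcc=1e-6):
    """Composite index by exhaustive pair enumeration.

    ``member_rows`` / ``nonmember_rows`` are lists of per-gene sample
    lists (already standardized).  Returns (sd_d, pcc_d, pcc_o, ci).
    """
    m = len(member_rows)
    sd_d = sum(sample_sd(r) for r in member_rows) / m
    pairs = [(i, j) for i in range(m) for j in range(i + 1, m)]
    pcc_d = sum(abs(pearson(member_rows[i], member_rows[j])) for i, j in pairs) / len(pairs)
    cross = [
        abs(pearson(mr, nr)) for mr in member_rows for nr in nonmember_rows
    ]
    pcc_o = sum(cross) / len(cross)
    ci = sd_d * pcc_d / max(pcc_o, eps_pcc)
    return sd_d, pcc_d, pcc_o, ci
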