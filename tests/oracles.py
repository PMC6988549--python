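"""Independent brute-force oracles shared by unit and acceptance tests.

These re-derive expected results with explicit loops and recounting only —
they deliberately share no code with the package implementation.
"""

import numpy as np

from popstruct import MISSING


def brute_force_cascade(codes, steps):
    """Survivors of the sequential individual/locus cascade, by recounting."""
    codes = np.asarray(codes)
    rows = list(range(codes.shape[0]))
    cols = list(range(codes.shape[1]))
    for step in steps:
        surv_rows = []
        for i in rows:
            miss = sum(1 for j in cols if codes[i, j] == MISSING)
            if len(cols) == 0 or miss / len(cols) <= step.max_individual_missing:
                surv_rows.append(i)
        rows = surv_rows
        surv_cols = []
        for j in cols:
            vals = [codes[i, j] for i in rows if codes[i, j] != MISSING]
            n_obs = len(vals)
            p = sum(vals) / (2 * n_obs) if n_obs else 0.0
            maf = min(p, 1 - p)
            callrate = n_obs / len(rows) if rows else 0.0
            if step.min_maf is not None and maf < step.min_maf:
                continue
            if (step.min_locus_callrate is not None
                    and callrate < step.min_locus_callrate):
                continue
            surv_cols.append(j)
        cols = surv_cols
    return rows, cols


def random_violation_matrix(rng, n=20, m=50):
    """Random genotype matrix with planted missingness and rare-allele loci."""
    codes = rng.choice([0, 1, 2], size=(n, m),
                       p=[0.45, 0.35, 0.2]).astype(np.int8)
    for j in rng.choice(m, size=m // 5, replace=False):
        codes[:, j] = 0
        if rng.random() < 0.5:
            codes[rng.integers(n), j] = 1
    miss = rng.random((n, m)) < rng.uniform(0.0, 0.25)
    for i in rng.choice(n, size=n // 4, replace=False):
        miss[i, rng.random(m) < rng.uniform(0.3, 0.9)] = True
    for j in rng.choice(m, size=m // 6, replace=False):
        miss[rng.random(n) < rng.uniform(0.2, 0.6), j] = True
    codes[miss] = MISSING
    return codes
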