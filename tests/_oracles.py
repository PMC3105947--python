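"""Independent oracles used by the tests.

These are deliberately written without reference to the package internals:
a brute-force OLS likelihood-ratio statistic, a forward simulation of
sib-mated RI pedigrees to fixation, and a permutation p-value for a
correlation coefficient.
"""
from __future__ import annotations

import numpy as np


def ols_lrs(y: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """LRS and slope of the trait-on-dosage regression via lstsq.

    LRS = n * ln(RSS0/RSS1) with RSS0 from the intercept-only model.
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    design = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    rss1 = float(resid @ resid)
    rss0 = float(((y - y.mean()) ** 2).sum())
    return len(y) * np.log(rss0 / rss1), float(beta[1])


def ri_pedigree_recombinant_fraction(
    r: float, n_lines: int, seed: int, max_gen: int = 500
) -> float:
    """Fraction of sib-mated RI lines fixed recombinant between two loci.

    Starting from F1 sibs (both carrying the two parental haplotypes at two
    loci with meiotic recombination fraction ``r``), brother-sister mating
    proceeds until every line is homozygous and identical at both loci. The
    analytic limit is R = 4r/(1+6r).
    """
    rng = np.random.default_rng(seed)
    # h[line, individual, haplotype, locus]; parental haplotypes (0,0) and (1,1)
    h = np.zeros((n_lines, 2, 2, 2), dtype=np.int8)
    h[:, :, 1, :] = 1
    active = np.ones(n_lines, dtype=bool)
    for _ in range(max_gen):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        m = np.arange(idx.size)
        new = np.empty((idx.size, 2, 2, 2), dtype=np.int8)
        for child in range(2):
            for parent in range(2):
                ph = h[idx, parent]  # (m, 2 haplotypes, 2 loci)
                first = rng.integers(0, 2, size=idx.size)
                rec = rng.random(idx.size) < r
                second = np.where(rec, 1 - first, first)
                new[:, child, parent, 0] = ph[m, first, 0]
                new[:, child, parent, 1] = ph[m, second, 1]
        h[idx] = new
        flat = h[idx].reshape(idx.size, 4, 2)
        fixed = (flat == flat[:, :1, :]).all(axis=(1, 2))
        active[idx[fixed]] = False
    flat = h.reshape(n_lines, 4, 2)
    if not (flat == flat[:, :1, :]).all():
        raise RuntimeError("pedigree simulation did not reach fixation")
    fixed_hap = flat[:, 0, :]
    return float((fixed_hap[:, 0] != fixed_hap[:, 1]).mean())


def permutation_corr_p(x: np.ndarray, y: np.ndarray, n_perm: int, seed: int) -> float:
    """Two-sided permutation p-value for the Pearson correlation of x and y."""
    rng = np.random.default_rng(seed)
    obs = abs(np.corrcoef(x, y)[0, 1])
    count = 0
    for _ in range(n_perm):
        count += abs(np.corrcoef(x, rng.permutation(y))[0, 1]) >= obs
    return (count + 1) / (n_perm + 1)
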