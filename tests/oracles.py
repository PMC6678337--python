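"""Independent reference implementations used only as test oracles.

Deliberately written as plain loops over cells/classes/genes/pairs, with
no shared code with the package, so that agreement is evidence and not
tautology.
"""

import math
from itertools import combinations

import numpy as np
from scipy.stats import norm


def posterior_oracle(x, genes, class_genes, mu_high, mu_low, sd_high, sd_low, tau):
    """Direct enumeration of p(class | cell) for every cell.

    x: genes x cells array in the order of `genes`.  class_genes: list
    (one entry per class, same order as tau) of the sets of genes that
    class draws from the high mode; the unknown class is an empty set.
    Returns (posterior cells x classes, total log marginal likelihood).
    """
    n_cells = x.shape[1]
    n_classes = len(class_genes)
    post = np.zeros((n_cells, n_classes))
    total_ll = 0.0
    for j in range(n_cells):
        joint = []
        for k in range(n_classes):
            lik = 1.0
            for gi, g in enumerate(genes):
                if g in class_genes[k]:
                    lik *= norm.pdf(x[gi, j], mu_high[gi], sd_high[gi])
                else:
                    lik *= norm.pdf(x[gi, j], mu_low[gi], sd_low[gi])
            joint.append(tau[k] * lik)
        marginal = sum(joint)
        total_ll += math.log(marginal)
        post[j] = np.asarray(joint) / marginal
    return post, total_ll


def weighted_moments_oracle(values, weights):
    """Hand-rolled responsibility-weighted mean and sd for one gene/mode."""
    w = np.asarray(weights, float)
    x = np.asarray(values, float)
    mu = float((w * x).sum() / w.sum())
    var = float((w * (x - mu) ** 2).sum() / w.sum())
    return mu, math.sqrt(var)


def ari_pair_counting(a, b):
    """Adjusted Rand index by brute force over all cell pairs, in percent."""
    a = list(a)
    b = list(b)
    n = len(a)
    pairs = list(combinations(range(n), 2))
    s_a = sum(1 for i, j in pairs if a[i] == a[j])
    s_b = sum(1 for i, j in pairs if b[i] == b[j])
    s_ab = sum(1 for i, j in pairs if a[i] == a[j] and b[i] == b[j])
    total = len(pairs)
    expected = s_a * s_b / total if total else 0.0
    max_index = (s_a + s_b) / 2.0
    if max_index == expected:  # both partitions trivial -> define as perfect
        return 100.0
    return 100.0 * (s_ab - expected) / (max_index - expected)
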