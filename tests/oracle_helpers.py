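"""Independent oracle routes shared by the AMOVA tests.

The allele-identity distance between two gene copies equals half the squared
Euclidean distance between their one-hot allele encodings, so the AMOVA sums
of squares can be recomputed from coordinate deviations without ever forming
pairwise distances.
"""

import numpy as np

from scutpop.core_data import GenotypeTable, MISSING


def one_hot_copies(gt: GenotypeTable) -> np.ndarray:
    blocks = []
    for l in range(gt.n_loci):
        copies = gt.genotypes[:, l, :].reshape(-1)
        alleles = sorted(set(copies.tolist()) - {MISSING})
        X = np.zeros((len(copies), len(alleles)))
        for k, a in enumerate(alleles):
            X[copies == a, k] = 1.0
        blocks.append(X)
    return np.hstack(blocks)


def oracle_ss(X: np.ndarray, labels: np.ndarray):
    """(SS_total, SS_within) by coordinate deviations (factor 1/2 matches the
    allele-identity scale)."""
    ss_tot = 0.5 * float(np.sum((X - X.mean(axis=0)) ** 2))
    ss_w = 0.0
    for g in np.unique(labels):
        sub = X[labels == g]
        ss_w += 0.5 * float(np.sum((sub - sub.mean(axis=0)) ** 2))
    return ss_tot, ss_w
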