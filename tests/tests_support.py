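"""Independent brute-force oracles shared by the acceptance tests."""

import itertools

import numpy as np


def nodf_oracle_matrix(mat: np.ndarray) -> float:
    """NODF straight from its definition, for a binary incidence matrix."""
    terms = []
    for axis_mat in (np.asarray(mat), np.asarray(mat).T):
        deg = axis_mat.sum(axis=1)
        for i, j in itertools.combinations(range(axis_mat.shape[0]), 2):
            hi, lo = (i, j) if deg[i] > deg[j] else (j, i)
            if deg[i] == deg[j] or deg[lo] == 0:
                terms.append(0.0)
            else:
                shared = np.sum(axis_mat[hi] * axis_mat[lo])
                terms.append(100.0 * shared / deg[lo])
    return float(np.mean(terms)) if terms else 0.0
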