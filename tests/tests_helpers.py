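"""Brute-force oracles shared across test modules."""

import numpy as np


def naive_background_kernel(cod, tr, which):
    """Explicit pair enumeration of a background kernel (small p only)."""
    U_A, U_D = cod.U_A, cod.U_D
    p = U_A.shape[1]
    N = U_A.shape[0]
    G = np.zeros((N, N))
    if which in ("AA", "DD"):
        U = U_A if which == "AA" else U_D
        for i in range(p):
            for j in range(i + 1, p):
                v = U[:, i] * U[:, j]
                G += np.outer(v, v)
    elif which == "AD":
        for i in range(p):
            for j in range(p):
                if i != j:
                    v = U_A[:, i] * U_D[:, j]
                    G += np.outer(v, v)
    else:
        G = U_D @ U_D.T
    K = np.asarray(tr.T @ G @ tr.T.T)
    return K / (np.trace(K) / tr.n_hybrids)
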