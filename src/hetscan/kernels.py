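"""Genomic relationship kernels for the heterosis mixed model.

Two families of kernels are built here:

* Background kernels K_D, K_AA, K_AD, K_DD capturing dominance and digenic
  epistatic relatedness on the MPH scale.  The epistatic design matrices
  have O(p^2) columns and are never materialized; their cross-products are
  obtained from Hadamard identities on the single-marker codings, e.g.

      U_AA U_AA' = 1/2 [ (U_A U_A') o (U_A U_A') - (U_A o U_A)(U_A o U_A)' ]

  where "o" is the entrywise product.  Background kernels use the
  frequency-centered codings U_A / U_D so the variance components match the
  classical dominance / epistatic variance decomposition.

* Per-marker heterosis kernels H_i = Z_i Z_i' / c_i, the covariance of the
  net heterotic effect of marker i under i.i.d. component effects.  Z_i has
  4p-3 columns (d_i and the aa/ad/da/dd interactions of i with every other
  marker) and is likewise never materialized at scale: with the pair
  cross-products S = M_A M_A' + M_D M_D' precomputed once, each H_i costs
  O(n (n+r)).  H_i deliberately uses the raw M_A / M_D codings -- the
  heterotic effect is defined on the raw parameterization, whereas the
  background kernels are centered; the asymmetry is intentional.

All kernels are trace-normalized to n (c = trace / n computed after the MPH
transform T is applied) and checked for symmetry / positive
semi-definiteness.  The Delta constant mean(diag(K)) - mean(K) converts a
variance component into variance explained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from hetscan.popdata import CodingMatrices, MPHTransform

__all__ = [
    "KernelSet", "HeterosisKernel", "background_kernels",
    "pair_cross_products", "heterosis_kernel", "heterosis_kernel_oracle",
    "heterotic_effect_piecewise", "kernel_delta",
]

BACKGROUND_NAMES = ("D", "AA", "AD", "DD")

#: minimum-eigenvalue tolerance (times n) before a kernel is declared indefinite
PSD_TOL = 1e-8


class KernelError(ValueError):
    """Raised for degenerate or numerically indefinite kernels."""


def kernel_delta(K: np.ndarray) -> float:
    """mean(diag(K)) - mean(K): converts a variance component into PVE units."""
    K = np.asarray(K)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise KernelError("kernel must be square")
    return float(np.mean(np.diag(K)) - np.mean(K))


def _check_psd(K: np.ndarray, name: str) -> None:
    n = K.shape[0]
    if not np.allclose(K, K.T, atol=1e-10 * max(1.0, np.abs(K).max())):
        raise KernelError(f"kernel {name} is not symmetric")
    w_min = float(np.linalg.eigvalsh(K)[0])
    if w_min < -PSD_TOL * n:
        raise KernelError(
            f"kernel {name} is numerically indefinite (min eigenvalue {w_min:.3e})")


def _normalize(G: np.ndarray, transform: MPHTransform, name: str,
               validate: bool) -> tuple[np.ndarray, float]:
    """Apply T . T', trace-normalize to n, optionally check PSD."""
    T = transform.T
    K = (T @ (T @ G).T).T if sparse.issparse(T) else T @ G @ T.T
    K = np.asarray(K)
    K = 0.5 * (K + K.T)
    n = K.shape[0]
    c = float(np.trace(K) / n)
    if c <= 1e-12 * max(1.0, np.abs(G).max()):
        raise KernelError(
            f"kernel {name} is degenerate (normalizer c = {c:.3e}); "
            "the corresponding coding carries no variation in this population")
    K /= c
    if validate:
        _check_psd(K, name)
    return K, c


@dataclass
class KernelSet:
    """Normalized background kernels plus residual covariance and constants.

    ``kernels`` maps 'D'/'AA'/'AD'/'DD' to n x n trace-normalized matrices;
    ``c`` holds the trace normalizers, ``delta`` the PVE conversion
    constants; ``R`` is the MPH residual covariance T T'.
    """

    kernels: dict[str, np.ndarray]
    c: dict[str, float]
    delta: dict[str, float]
    R: np.ndarray

    @property
    def n(self) -> int:
        return self.R.shape[0]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.kernels[name]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.kernels)

    def save(self, directory, panel_hash: str | None = None) -> None:
        """Export kernels as dense .npy files with a JSON sidecar.

        The sidecar records n, the normalizers, the Delta constants and an
        optional marker-panel hash so a resumed scan can verify it is
        using the kernels it thinks it is.
        """
        import hashlib
        import json
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for name, K in self.kernels.items():
            np.save(d / f"K_{name}.npy", K)
        np.save(d / "R.npy", self.R)
        digests = {name: hashlib.sha256(K.tobytes()).hexdigest()[:16]
                   for name, K in self.kernels.items()}
        sidecar = {"n": self.n, "c": self.c, "delta": self.delta,
                   "kernel_sha256": digests, "panel_hash": panel_hash}
        (d / "kernels.json").write_text(json.dumps(sidecar, indent=2) + "\n")

    @classmethod
    def load(cls, directory, panel_hash: str | None = None) -> "KernelSet":
        import hashlib
        import json
        from pathlib import Path

        d = Path(directory)
        sidecar = json.loads((d / "kernels.json").read_text())
        if panel_hash is not None and sidecar.get("panel_hash") not in (None, panel_hash):
            raise KernelError("kernel sidecar was built for a different marker panel")
        kernels = {name: np.load(d / f"K_{name}.npy")
                   for name in sidecar["kernel_sha256"]}
        for name, K in kernels.items():
            if hashlib.sha256(K.tobytes()).hexdigest()[:16] != \
                    sidecar["kernel_sha256"][name]:
                raise KernelError(f"kernel {name} does not match its sidecar hash")
        return cls(kernels=kernels, c=sidecar["c"], delta=sidecar["delta"],
                   R=np.load(d / "R.npy"))


@dataclass
class HeterosisKernel:
    """Per-marker kernel H_i = Z_i Z_i' / c_i with its normalizer and Delta."""

    index: int
    H: np.ndarray
    c: float
    delta: float


def background_kernels(codings: CodingMatrices, transform: MPHTransform,
                       validate: bool = True) -> KernelSet:
    """Build the four background kernels K_D, K_AA, K_AD, K_DD.

    Epistatic cross-products are assembled from Hadamard identities on
    U_A U_A' and U_D U_D' at O((n+r)^2 p) total cost; each kernel is then
    transformed to the MPH scale and trace-normalized to n.
    """
    p = codings.n_markers
    if p < 2:
        raise KernelError("at least two markers required for epistatic kernels")
    if transform.n_hybrids < 2:
        raise KernelError("at least two hybrids required")
    U_A, U_D = codings.U_A, codings.U_D
    A = U_A @ U_A.T
    D = U_D @ U_D.T
    G = {}
    G["D"] = D
    G["AA"] = 0.5 * (A * A - (U_A ** 2) @ (U_A ** 2).T)
    W = U_A * U_D
    G["AD"] = A * D - W @ W.T           # both orderings (i,j) and (j,i)
    G["DD"] = 0.5 * (D * D - (U_D ** 2) @ (U_D ** 2).T)

    kernels, cs, deltas = {}, {}, {}
    for name in BACKGROUND_NAMES:
        K, c = _normalize(G[name], transform, name, validate)
        kernels[name] = K
        cs[name] = c
        deltas[name] = kernel_delta(K)
    return KernelSet(kernels=kernels, c=cs, delta=deltas, R=transform.R)


def pair_cross_products(codings: CodingMatrices) -> np.ndarray:
    """Precompute S = M_A M_A' + M_D M_D', shared by every heterosis kernel."""
    return codings.M_A @ codings.M_A.T + codings.M_D @ codings.M_D.T


def heterosis_kernel(i: int, codings: CodingMatrices, transform: MPHTransform,
                     S: np.ndarray | None = None) -> HeterosisKernel:
    """Fast construction of the heterosis kernel H_i for marker i.

    With S = M_A M_A' + M_D M_D' precomputed, the sum over the 4(p-1)
    interaction columns of Z_i collapses to

        Z_i Z_i' = (T l_i)(T l_i)'
                 + 1/4 T [ D_m S D_m + D_l S D_l - self-pair terms ] T'

    where m = m_i, l = l_i, D_v = diag(v); the self-pair terms remove the
    j = i contributions (the interaction sums run over j != i).  The cost is
    O(n (n+r)) per marker, O(n (n+r) p) for a whole genome scan.
    """
    p = codings.n_markers
    if not 0 <= i < p:
        raise KernelError(f"marker index {i} out of range [0, {p})")
    if S is None:
        S = pair_cross_products(codings)
    T = transform.T
    m = codings.M_A[:, i]
    l = codings.M_D[:, i]

    Tl = np.asarray(T @ l)
    # T D_v S D_v T' via column-scaled copies of the sparse transform
    Tm_s = T.multiply(m[None, :]).tocsr()
    Tl_s = T.multiply(l[None, :]).tocsr()
    P = np.asarray(Tm_s @ S @ Tm_s.T.toarray()) + np.asarray(Tl_s @ S @ Tl_s.T.toarray())
    # self-pair (j = i) corrections: m*m and l*l once, m*l twice (ad + da)
    v1 = np.asarray(T @ (m * m))
    v2 = np.asarray(T @ (m * l))
    v3 = np.asarray(T @ (l * l))
    N = (np.outer(Tl, Tl)
         + 0.25 * (P - np.outer(v1, v1) - 2.0 * np.outer(v2, v2)
                   - np.outer(v3, v3)))
    n = N.shape[0]
    c = float(np.trace(N) / n)
    scale = max(1.0, float(np.abs(S).max()))
    if c <= 1e-12 * scale:
        raise KernelError(
            f"degenerate heterosis kernel for marker {i} (c = {c:.3e}); "
            "the marker carries no heterotic design variation")
    H = N / c
    H = 0.5 * (H + H.T)
    return HeterosisKernel(index=i, H=H, c=c, delta=kernel_delta(H))


#: largest marker count for which the oracle will materialize Z_i
ORACLE_MAX_MARKERS = 2000


def heterosis_kernel_oracle(i: int, codings: CodingMatrices,
                            transform: MPHTransform) -> HeterosisKernel:
    """Reference construction of H_i from the explicit n x (4p-3) design Z_i.

    Builds the columns T l_i, (1/2) T(m_i o m_j), (1/2) T(m_i o l_j),
    (1/2) T(l_i o m_j), (1/2) T(l_i o l_j) for every j != i and returns
    Z_i Z_i' / c_i.  Quadratic in p; guarded to small marker panels and used
    as an independent check of the fast path.
    """
    p = codings.n_markers
    if p > ORACLE_MAX_MARKERS:
        raise KernelError(
            f"oracle limited to p <= {ORACLE_MAX_MARKERS} markers "
            f"(got {p}); use heterosis_kernel for the fast path")
    if not 0 <= i < p:
        raise KernelError(f"marker index {i} out of range [0, {p})")
    T = transform.T
    M_A, M_D = codings.M_A, codings.M_D
    m_i, l_i = M_A[:, i], M_D[:, i]
    cols = [np.asarray(T @ l_i)]
    for j in range(p):
        if j == i:
            continue
        for v in (m_i * M_A[:, j], m_i * M_D[:, j],
                  l_i * M_A[:, j], l_i * M_D[:, j]):
            cols.append(0.5 * np.asarray(T @ v))
    Z = np.column_stack(cols)
    n = Z.shape[0]
    c = float(np.sum(Z * Z) / n)          # trace(Z Z') / n
    if c <= 0.0:
        raise KernelError(f"degenerate heterosis kernel for marker {i} (c = 0)")
    H = Z @ Z.T / c
    return HeterosisKernel(index=i, H=H, c=c, delta=kernel_delta(H))


def heterotic_effect_piecewise(i: int, parent1_codes: np.ndarray,
                               parent2_codes: np.ndarray, d_i: float,
                               aa: np.ndarray, ad_i_dot: np.ndarray,
                               ad_dot_i: np.ndarray, dd: np.ndarray) -> float:
    """Heterotic effect of marker i for one hybrid, by the four-case formula.

    The case depends on the parental genotype pattern at i (parent codes
    must be inbred, i.e. in {0, 2}).  ``aa[j]``, ``ad_i_dot[j]`` (additive
    of i x dominance of j), ``ad_dot_i[j]`` (dominance of i x additive of j)
    and ``dd[j]`` are the interaction effects with marker j; entries at
    j = i are ignored.  Used as an independent oracle for the design-matrix
    formulation.
    """
    p1 = np.asarray(parent1_codes, dtype=float)
    p2 = np.asarray(parent2_codes, dtype=float)
    if np.any(~np.isin(p1, (0.0, 2.0))) or np.any(~np.isin(p2, (0.0, 2.0))):
        raise KernelError("piecewise heterotic effect requires inbred parents "
                          "(codes in {0, 2}) at every marker")
    p = p1.shape[0]
    idx = np.arange(p)
    other = idx != i
    r20 = (p1 == 2) & (p2 == 0) & other
    r02 = (p1 == 0) & (p2 == 2) & other
    r22 = (p1 == 2) & (p2 == 2) & other
    r00 = (p1 == 0) & (p2 == 0) & other
    het = r20 | r02

    aa = np.asarray(aa, dtype=float)
    ad_i_dot = np.asarray(ad_i_dot, dtype=float)
    ad_dot_i = np.asarray(ad_dot_i, dtype=float)
    dd = np.asarray(dd, dtype=float)

    k1, k2 = p1[i], p2[i]
    if k1 == 2 and k2 == 0:
        return float(d_i - 0.5 * aa[r20].sum() + 0.5 * aa[r02].sum()
                     + 0.5 * ad_dot_i[r22].sum() - 0.5 * ad_dot_i[r00].sum()
                     + 0.5 * dd[het].sum())
    if k1 == 0 and k2 == 2:
        return float(d_i - 0.5 * aa[r02].sum() + 0.5 * aa[r20].sum()
                     + 0.5 * ad_dot_i[r22].sum() - 0.5 * ad_dot_i[r00].sum()
                     + 0.5 * dd[het].sum())
    if k1 == 2 and k2 == 2:
        return float(0.5 * ad_i_dot[het].sum())
    return float(-0.5 * ad_i_dot[het].sum())
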