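"""Relationship matrices and kernels for whole-genome prediction.

Three families of line-by-line covariance structures feed the Bayesian
models:

* the genomic relationship matrix (VanRaden method 1) from SNP dosages or
  from haplotype-allele incidence columns,
* the pedigree additive relationship matrix (see :mod:`gbspredict.pedigree`),
* Gaussian kernels K_h = exp(-h d^2 / median(d^2)) on Euclidean genotype
  distances, one per bandwidth, for RKHS kernel averaging.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .pedigree import Pedigree, a_matrix as _a_matrix

DEFAULT_BANDWIDTHS = (0.2, 1.0, 5.0)
JITTER = 1e-6


@dataclasses.dataclass
class RelationshipMatrix:
    """Symmetric PSD line x line matrix with provenance metadata."""

    values: np.ndarray
    kind: str  # pedigree-A | genomic-G | haplotype-G | gaussian
    bandwidth: float | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("relationship matrix must be square")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("relationship matrix must be symmetric")
        self.values = (v + v.T) / 2.0

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def jittered(self, eps: float = JITTER) -> np.ndarray:
        return self.values + eps * np.eye(self.n)


KernelSet = dict[str, RelationshipMatrix]


def _check_kernel_set(ks: KernelSet) -> None:
    dims = {k.n for k in ks.values()}
    if len(dims) > 1:
        raise ValueError(f"kernel dimensions differ: {dims}")


def _project_psd(M: np.ndarray) -> np.ndarray:
    """Nearest-PSD projection (clip negative eigenvalues); needed for
    pairwise-complete estimators, which are not PSD in general."""
    vals, vecs = np.linalg.eigh((M + M.T) / 2.0)
    if vals[0] >= 0:
        return M
    vals = np.clip(vals, 0.0, None)
    return (vecs * vals) @ vecs.T


def grm_from_markers(X: np.ndarray) -> RelationshipMatrix:
    """VanRaden method-1 genomic relationship matrix.

    G = Z Z' / (2 sum p_j (1-p_j)) with Z = X - 2p and p the observed
    allele frequency; X must be a complete lines x markers dosage matrix
    (0..2), e.g. after expected-value imputation.
    """
    X = np.asarray(X, float)
    if np.isnan(X).any():
        return _grm_pairwise_complete(X)
    p = X.mean(axis=0) / 2.0
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all markers monomorphic: GRM denominator is zero")
    Z = X - 2.0 * p[None, :]
    return RelationshipMatrix(Z @ Z.T / denom, "genomic-G")


def _grm_pairwise_complete(X: np.ndarray) -> RelationshipMatrix:
    """GRM for nonimputed data: cross-products over pairwise-complete
    markers, rescaled by each pair's share of the full denominator."""
    obs = ~np.isnan(X)
    n_called = obs.sum(axis=0)
    if (n_called == 0).any():
        raise ValueError("all-missing marker in GRM input")
    p = np.nansum(X, axis=0) / (2.0 * n_called)
    w = p * (1.0 - p)
    denom_full = 2.0 * w.sum()
    if denom_full <= 0:
        raise ValueError("all markers monomorphic: GRM denominator is zero")
    Z = np.where(obs, X - 2.0 * p[None, :], 0.0)
    num = Z @ Z.T
    # per-pair denominator: 2 * sum of w over markers called in both lines
    shared_w = (obs * w[None, :]) @ obs.T * 2.0
    shared_w[shared_w <= 0] = np.nan
    G = num / shared_w
    G = np.nan_to_num(G, nan=0.0)
    return RelationshipMatrix(_project_psd((G + G.T) / 2.0), "genomic-G")


def grm_from_haplotypes(H: np.ndarray) -> RelationshipMatrix:
    """Genomic relationship from a lines x haplotype-allele 0/1 incidence
    matrix: G_H = W W' / c, W column-centred incidence,
    c = sum q_j (1 - q_j) over haplotype-allele frequencies."""
    H = np.asarray(H, float)
    q = H.mean(axis=0)
    c = np.sum(q * (1.0 - q))
    if c <= 0:
        raise ValueError("zero-variance haplotype incidence (single cluster everywhere)")
    W = H - q[None, :]
    return RelationshipMatrix(W @ W.T / c, "haplotype-G")


def a_matrix(ped: Pedigree, line_ids: list[str] | None = None) -> RelationshipMatrix:
    """Pedigree additive relationship matrix (tabular method; DH diagonal 2)."""
    return RelationshipMatrix(_a_matrix(ped, line_ids), "pedigree-A")


def _squared_distances(X: np.ndarray) -> np.ndarray:
    sq = np.sum(X * X, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.fill_diagonal(d2, 0.0)
    return np.maximum(d2, 0.0)


def _squared_distances_pairwise(X: np.ndarray) -> np.ndarray:
    """Squared distances over pairwise-complete markers, rescaled by the
    fraction of complete pairs (missing-data convention for nonimputed GBS)."""
    obs = ~np.isnan(X)
    X0 = np.where(obs, X, 0.0)
    sq = X0 * X0
    cross = X0 @ X0.T
    # sum over shared markers of x_i^2 and x_j^2
    si = sq @ obs.T
    d2 = si + si.T - 2.0 * cross
    n_shared = (obs @ obs.T).astype(float)
    m = X.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        d2 = d2 * (m / n_shared)
    d2 = np.nan_to_num(d2, nan=0.0)
    np.fill_diagonal(d2, 0.0)
    return np.maximum(d2, 0.0)


def gaussian_kernels(
    X: np.ndarray, bandwidths: tuple[float, ...] = DEFAULT_BANDWIDTHS,
    scale_to_unit: bool = True,
) -> KernelSet:
    """Gaussian kernels on Euclidean genotype distances, one per bandwidth.

    K_h(i,i') = exp(-h * d^2(i,i') / median(d^2)), the median taken over
    off-diagonal pairs so the bandwidth grid is scale-free.  Genotype
    dosages are mapped to [0,1] before computing distances.  Missing values
    (NaN) are handled by pairwise-complete distances rescaled to the full
    marker count.
    """
    if any(h <= 0 for h in bandwidths):
        raise ValueError("bandwidths must be positive")
    X = np.asarray(X, float)
    if scale_to_unit:
        X = X / 2.0
    had_missing = bool(np.isnan(X).any())
    d2 = _squared_distances_pairwise(X) if had_missing else _squared_distances(X)
    off = d2[np.triu_indices_from(d2, k=1)]
    med = np.median(off)
    if med <= 0:
        raise ValueError("median off-diagonal distance is zero (identical lines)")
    out = {}
    for h in bandwidths:
        K = np.exp(-h * d2 / med)
        if had_missing:
            K = _project_psd(K)
        out[f"K_h{h:g}"] = RelationshipMatrix(K, "gaussian", bandwidth=h)
    return out


def min_eigenvalue(K: RelationshipMatrix | np.ndarray) -> float:
    v = K.values if isinstance(K, RelationshipMatrix) else np.asarray(K)
    return float(np.linalg.eigvalsh(v)[0])
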