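"""Haplotype-library imputation for high-missingness inbred genotype data.

At every marker, lines are partitioned into clusters of individuals that
plausibly share the local haplotype: two lines may share a cluster only if,
within a window of flanking markers, they show at most ``max_disagreements``
opposing homozygous calls (0 vs 2; positions where either line is missing
are uninformative and never count).  Within a cluster, a line missing the
focal call receives the cluster consensus when at least one member is
called ("technically missing"); if every member is missing, the call is
left missing ("biologically missing" — presence/absence variation rather
than low coverage).  The sweep moves the focal marker and its window one
marker at a time along each chromosome.

The per-marker clusterings double as haplotype alleles: the lines x
(marker, cluster) incidence matrix can replace SNP dosages when building
relationship matrices for prediction.

Cluster formation is greedy seed-and-extend in line input order with
complete linkage (a line joins the first cluster compatible with *every*
current member), which is deterministic and guarantees the pairwise
property; ``linkage="seed"`` relaxes this to compatibility with the
cluster's founding member only.  Singleton clusters are allowed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from numba import njit
from sklearn.base import BaseEstimator, TransformerMixin

from .genotype import MISSING, GenotypeMatrix

PROV_CALLED = 0
PROV_IMPUTED = 1
PROV_BIO_MISSING = 2


@dataclasses.dataclass
class ImputeParams:
    """Window size (markers per side) and pairwise disagreement tolerance."""

    flank_size: int = 1000
    max_disagreements: int = 4
    linkage: str = "complete"

    def __post_init__(self) -> None:
        if self.flank_size < 1:
            raise ValueError("flank_size must be >= 1")
        if self.max_disagreements < 0:
            raise ValueError("max_disagreements must be >= 0")
        if self.linkage not in ("complete", "seed"):
            raise ValueError("linkage must be 'complete' or 'seed'")


@dataclasses.dataclass
class HaplotypeClustering:
    """Per-marker partition of lines into haplotype clusters.

    ``labels[i, j]`` is the cluster id of line i at marker j (ids are dense
    per marker, in order of cluster creation).
    """

    labels: np.ndarray  # (n_lines, n_markers) int32
    line_ids: list[str]
    marker_ids: list[str]
    chrom: np.ndarray

    def n_clusters(self) -> np.ndarray:
        return self.labels.max(axis=0) + 1

    def incidence(self, stride: int = 1) -> tuple[np.ndarray, list[str]]:
        """Lines x haplotype-allele 0/1 incidence over every ``stride``-th
        marker.  One column per (marker, cluster); each line carries exactly
        one allele per sampled marker."""
        cols, names = [], []
        for j in range(0, self.labels.shape[1], stride):
            lab = self.labels[:, j]
            k = lab.max() + 1
            block = np.zeros((len(lab), k), dtype=np.int8)
            block[np.arange(len(lab)), lab] = 1
            cols.append(block)
            names.extend(f"{self.marker_ids[j]}.c{c}" for c in range(k))
        return np.concatenate(cols, axis=1), names

    def to_frame(self):
        import pandas as pd

        n, m = self.labels.shape
        return pd.DataFrame({
            "marker": np.repeat(self.marker_ids, n),
            "line": np.tile(self.line_ids, m),
            "cluster": self.labels.T.ravel(),
        })


@dataclasses.dataclass
class ImputedGenotypes:
    """Imputed calls plus a provenance mask (called/imputed/biologically
    missing) covering every cell."""

    geno: GenotypeMatrix
    provenance: np.ndarray  # uint8, PROV_* codes

    @property
    def n_imputed(self) -> int:
        return int((self.provenance == PROV_IMPUTED).sum())

    def missing_summary(self):
        """Per-chromosome % missing before/after imputation (report shaped
        like the marker-edit tables)."""
        import pandas as pd

        rows = []
        before = (self.provenance != PROV_CALLED)
        after = self.geno.missing_mask
        for c in self.geno.chromosomes():
            on_c = self.geno.chrom == c
            rows.append({
                "chrom": c,
                "n_markers": int(on_c.sum()),
                "pct_missing_before": 100.0 * before[:, on_c].mean(),
                "pct_missing_after_imputation": 100.0 * after[:, on_c].mean(),
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reference (pure python) operations — also the small-scale API
# ---------------------------------------------------------------------------

def window_indices(marker: int, flank: int, lo: int, hi: int) -> np.ndarray:
    """Flanking-window marker indices around ``marker`` (excluded), truncated
    to the chromosome bounds [lo, hi)."""
    left = np.arange(max(lo, marker - flank), marker)
    right = np.arange(marker + 1, min(hi, marker + flank + 1))
    return np.concatenate([left, right])


def count_disagreements(line_a: int, line_b: int, window: np.ndarray,
                        geno: GenotypeMatrix) -> int:
    """Opposing-homozygote count between two lines over a marker window;
    missing calls never disagree."""
    if len(window) == 0:
        import warnings
        warnings.warn("empty disagreement window")
        return 0
    a = geno.calls[line_a, window]
    b = geno.calls[line_b, window]
    return int(np.sum(((a == 0) & (b == 2)) | ((a == 2) & (b == 0))))


def cluster_at_marker(geno: GenotypeMatrix, marker: int,
                      params: ImputeParams | None = None) -> np.ndarray:
    """Greedy haplotype clustering of all lines at one marker; returns dense
    cluster labels in line order."""
    params = params or ImputeParams()
    chrom = geno.chrom[marker]
    on_c = np.flatnonzero(geno.chrom == chrom)
    lo, hi = on_c[0], on_c[-1] + 1
    win = window_indices(marker, params.flank_size, lo, hi)
    n = geno.n_lines
    labels = np.full(n, -1, dtype=np.int32)
    members: list[list[int]] = []
    for i in range(n):
        for k, mem in enumerate(members):
            check = mem if params.linkage == "complete" else mem[:1]
            if all(count_disagreements(i, j, win, geno) <= params.max_disagreements
                   for j in check):
                labels[i] = k
                mem.append(i)
                break
        else:
            labels[i] = len(members)
            members.append([i])
    return labels


def impute_at_marker(geno: GenotypeMatrix, marker: int,
                     partition: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Apply the cluster-consensus rule at one marker.

    Returns (calls, provenance) for that marker column.  Consensus is the
    majority homozygote among called members; an exact tie leaves the call
    missing.
    """
    partition = np.asarray(partition)
    if len(partition) != geno.n_lines:
        raise ValueError("partition must cover all lines")
    col = geno.calls[:, marker].copy()
    prov = np.where(col == MISSING, PROV_BIO_MISSING, PROV_CALLED).astype(np.uint8)
    for k in np.unique(partition):
        mem = np.flatnonzero(partition == k)
        calls = col[mem]
        n0 = int(np.sum(calls == 0))
        n2 = int(np.sum(calls == 2))
        if n0 + n2 == 0 or n0 == n2:
            continue  # biologically missing, or unresolvable tie
        consensus = 0 if n0 > n2 else 2
        miss = mem[calls == MISSING]
        col[miss] = consensus
        prov[miss] = PROV_IMPUTED
    return col, prov


# ---------------------------------------------------------------------------
# fast chromosome sweep
# ---------------------------------------------------------------------------

@njit(cache=True)
def _add_col(S, B, s, sign):  # pragma: no cover - exercised via sweep
    n = s.shape[0]
    for i in range(n):
        si = s[i]
        if si == 0:
            continue
        for j in range(i + 1, n):
            sj = s[j]
            if sj == 0:
                continue
            S[i, j] += sign * si * sj
            B[i, j] += sign
    # symmetric halves maintained lazily (upper triangle only)


@njit(cache=True)
def _sweep_chromosome(calls, flank, max_dis, complete_linkage,
                      out_calls, prov, labels):  # pragma: no cover
    """One-chromosome sweep: sliding pairwise disagreement counts, greedy
    clustering and consensus imputation at every marker."""
    n, m = calls.shape
    signed = np.zeros((n, m), np.int8)
    for i in range(n):
        for j in range(m):
            if calls[i, j] == 0:
                signed[i, j] = -1
            elif calls[i, j] == 2:
                signed[i, j] = 1
    S = np.zeros((n, n), np.int32)  # sum of products over window (upper tri)
    B = np.zeros((n, n), np.int32)  # both-called count over window
    lo = 0
    hi = -1  # inclusive window bound currently accumulated
    comp = np.zeros((n, n), np.bool_)  # cluster x line compatibility
    seed_of = np.zeros(n, np.int64)
    for focal in range(m):
        new_hi = min(m - 1, focal + flank)
        while hi < new_hi:
            hi += 1
            _add_col(S, B, signed[:, hi], 1)
        new_lo = max(0, focal - flank)
        while lo < new_lo:
            _add_col(S, B, signed[:, lo], -1)
            lo += 1
        sf = signed[:, focal]
        # greedy clustering
        n_clusters = 0
        for i in range(n):
            assigned = -1
            for k in range(n_clusters):
                if complete_linkage:
                    ok = comp[k, i]
                else:
                    j = seed_of[k]
                    a, b = (j, i) if j < i else (i, j)
                    d = ((B[a, b] - abs(sf[a]) * abs(sf[b]))
                         - (S[a, b] - sf[a] * sf[b])) // 2
                    ok = d <= max_dis
                if ok:
                    assigned = k
                    break
            if assigned == -1:
                assigned = n_clusters
                seed_of[assigned] = i
                n_clusters += 1
                for j in range(n):
                    comp[assigned, j] = True
            labels[i, focal] = assigned
            # update compatibility of this cluster with all lines
            for j in range(n):
                a, b = (j, i) if j < i else (i, j)
                if a == b:
                    continue
                d = ((B[a, b] - abs(sf[a]) * abs(sf[b]))
                     - (S[a, b] - sf[a] * sf[b])) // 2
                if d > max_dis:
                    comp[assigned, j] = False
        # consensus imputation per cluster
        for k in range(n_clusters):
            n0 = 0
            n2 = 0
            for i in range(n):
                if labels[i, focal] == k:
                    if calls[i, focal] == 0:
                        n0 += 1
                    elif calls[i, focal] == 2:
                        n2 += 1
            if n0 + n2 == 0 or n0 == n2:
                continue
            consensus = 0 if n0 > n2 else 2
            for i in range(n):
                if labels[i, focal] == k and calls[i, focal] == -1:
                    out_calls[i, focal] = consensus
                    prov[i, focal] = 1  # PROV_IMPUTED


def run_imputation(
    geno: GenotypeMatrix, params: ImputeParams | None = None,
) -> tuple[ImputedGenotypes, HaplotypeClustering]:
    """Sweep every marker of every chromosome; returns the imputed matrix
    with provenance and the per-marker clusterings."""
    params = params or ImputeParams()
    if np.any(geno.calls == 1):
        raise ValueError(
            "input contains heterozygous calls; apply set_heterozygotes_missing first")
    out = geno.copy()
    prov = np.where(geno.missing_mask, PROV_BIO_MISSING, PROV_CALLED).astype(np.uint8)
    labels = np.zeros(geno.calls.shape, dtype=np.int32)
    for c, idx in geno.chromosome_slices().items():
        sub = np.ascontiguousarray(geno.calls[:, idx])
        sub_out = sub.copy()
        sub_prov = prov[:, idx].copy()
        sub_lab = np.zeros(sub.shape, dtype=np.int32)
        _sweep_chromosome(sub, params.flank_size, params.max_disagreements,
                          params.linkage == "complete", sub_out, sub_prov, sub_lab)
        out.calls[:, idx] = sub_out
        prov[:, idx] = sub_prov
        labels[:, idx] = sub_lab
    clustering = HaplotypeClustering(labels, geno.line_ids, geno.marker_ids,
                                     geno.chrom)
    return ImputedGenotypes(out, prov), clustering


def haplotype_incidence(clustering: HaplotypeClustering,
                        stride: int = 1) -> tuple[np.ndarray, list[str]]:
    """Lines x haplotype-allele incidence matrix from per-marker clusters."""
    return clustering.incidence(stride)


class HaplotypeImputer(BaseEstimator, TransformerMixin):
    """Haplotype-clustering imputation as a scikit-learn transformer.

    Parameters
    ----------
    flank_size : int, default 1000
        Flanking markers per side of the focal marker (50 and 100 are the
        short/long-haplotype settings).
    max_disagreements : int, default 4
        Opposing-homozygote tolerance for two lines to share a cluster;
        0 gives the strict no-opposing-homozygotes reading.
    linkage : 'complete' or 'seed'
        Whether a joining line must be compatible with every cluster member
        or only with the founding member.
    stride : int, default 1
        Marker stride for the haplotype-allele incidence matrix.

    Attributes (after ``fit``)
    --------------------------
    imputed_ : ImputedGenotypes
    clustering_ : HaplotypeClustering
    n_imputed_ : int
    """

    def __init__(self, flank_size: int = 1000, max_disagreements: int = 4,
                 linkage: str = "complete", stride: int = 1):
        self.flank_size = flank_size
        self.max_disagreements = max_disagreements
        self.linkage = linkage
        self.stride = stride

    def _params(self) -> ImputeParams:
        return ImputeParams(self.flank_size, self.max_disagreements, self.linkage)

    def fit(self, X: GenotypeMatrix, y=None) -> "HaplotypeImputer":
        self.imputed_, self.clustering_ = run_imputation(X, self._params())
        self.n_imputed_ = self.imputed_.n_imputed
        return self

    def transform(self, X: GenotypeMatrix) -> GenotypeMatrix:
        """Return the imputed genotype matrix (fit data; the clustering is
        defined jointly on the full line set)."""
        if not hasattr(self, "imputed_"):
            raise ValueError("HaplotypeImputer is not fitted")
        return self.imputed_.geno

    def fit_transform(self, X: GenotypeMatrix, y=None, **kw) -> GenotypeMatrix:
        self.fit(X)
        return self.imputed_.geno

    def haplotype_incidence(self) -> tuple[np.ndarray, list[str]]:
        if not hasattr(self, "clustering_"):
            raise ValueError("HaplotypeImputer is not fitted")
        return self.clustering_.incidence(self.stride)
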