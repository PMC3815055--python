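"""Synthetic GBS breeding-population generator.

Emulates the study system the analysis pipeline assumes: a small set of
inbred founders crossed (and backcrossed) into full-sib doubled-haploid (DH)
families, genotyped by sequencing at low coverage so that a large fraction of
calls is missing, and phenotyped in a multi-environment replicated trial
with genotype, genotype-by-environment and plot-error variance components.

The default cross plan mirrors the structure of the reference breeding
experiment: eight founders (A..H) combined into ten full-sib DH families,
several of them backcrosses.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .genotype import MISSING, GenotypeMatrix
from .pedigree import Pedigree


@dataclasses.dataclass
class GeneticMap:
    """Marker map: per chromosome, ascending cM and bp positions."""

    chromosomes: list[tuple[str, np.ndarray, np.ndarray]]  # (id, cM, bp)

    def __post_init__(self) -> None:
        for name, cm, bp in self.chromosomes:
            cm, bp = np.asarray(cm, float), np.asarray(bp, np.int64)
            if len(cm) != len(bp):
                raise ValueError(f"chromosome {name}: cM/bp length mismatch")
            if np.any(np.diff(cm) <= 0) or np.any(np.diff(bp) <= 0):
                raise ValueError(f"chromosome {name}: positions must strictly increase")

    @classmethod
    def uniform(cls, n_chrom: int, n_markers: int, length_cm: float = 150.0,
                bp_per_cm: int = 1_000_000) -> "GeneticMap":
        """Evenly spaced markers; bp positions proportional to cM."""
        chroms = []
        for c in range(n_chrom):
            cm = np.linspace(0.0, length_cm, n_markers)
            bp = np.round(cm * bp_per_cm).astype(np.int64) + 1
            bp = np.maximum.accumulate(bp + np.arange(n_markers))  # strictly increasing
            chroms.append((str(c + 1), cm, bp))
        return cls(chroms)

    @property
    def n_markers(self) -> int:
        return sum(len(cm) for _, cm, _ in self.chromosomes)

    def marker_metadata(self):
        chrom = np.concatenate([[name] * len(cm) for name, cm, _ in self.chromosomes])
        cm = np.concatenate([c for _, c, _ in self.chromosomes])
        bp = np.concatenate([b for _, _, b in self.chromosomes])
        ids = [f"S{c}_{p}" for c, p in zip(chrom, bp)]
        return ids, chrom.astype(object), bp, cm


@dataclasses.dataclass
class CrossPlan:
    """Founders and family definitions: (parent1, parent2, backcross parent or
    None, family size)."""

    founders: list[str]
    families: list[tuple[str, str, str | None, int]]

    def __post_init__(self) -> None:
        fset = set(self.founders)
        for p1, p2, bc, size in self.families:
            if size < 1:
                raise ValueError("family size must be >= 1")
            for p in (p1, p2) + (() if bc is None else (bc,)):
                if p not in fset:
                    raise ValueError(f"unknown parent {p!r}")

    @classmethod
    def default_study(cls, scale: float = 1.0) -> "CrossPlan":
        """Eight founders, ten full-sib DH families (several backcrosses),
        family sizes proportional to the reference experiment (504 lines at
        scale 1)."""
        sizes = [64, 78, 29, 37, 108, 83, 29, 49, 9, 18]
        fams = [("A", "B", "B"), ("A", "C", "C"), ("A", "D", "D"),
                ("E", "F", "F"), ("E", "B", "B"), ("E", "C", "C"),
                ("E", "D", "D"), ("G", "B", "B"), ("H", "B", "B"),
                ("H", "D", "D")]
        founders = list("ABCDEFGH")
        families = [(p1, p2, bc, max(1, round(s * scale)))
                    for (p1, p2, bc), s in zip(fams, sizes)]
        return cls(founders, families)

    @property
    def n_lines(self) -> int:
        return sum(size for *_, size in self.families)


@dataclasses.dataclass
class PhenotypeParams:
    """Trait architecture and trial design for the phenotype simulator.

    sigma_g2 / sigma_ge2 / sigma_e2 are the genotype, GxE and plot-error
    variance components (trait units squared); n_env environments with n_rep
    replicates each; blocks of ``block_size`` lines within each (env, rep)
    with effects of scale ``block_sd``; ``env_sd`` scales environment main
    effects.
    """

    n_qtl: int = 100
    sigma_g2: float = 1.0
    sigma_ge2: float = 1.0
    sigma_e2: float = 2.0
    n_env: int = 4
    n_rep: int = 2
    block_sd: float = 0.5
    block_size: int = 25
    env_sd: float = 1.0
    mu: float = 10.0

    def __post_init__(self) -> None:
        if min(self.sigma_g2, self.sigma_ge2, self.sigma_e2) < 0:
            raise ValueError("variance components must be >= 0")
        if self.n_env < 1 or self.n_rep < 1:
            raise ValueError("need >= 1 environment and replicate")


def simulate_founders(n_founders: int, map: GeneticMap, maf_low: float = 0.1,
                      maf_high: float = 0.5, seed: int = 0) -> GenotypeMatrix:
    """Fully homozygous founder genotypes with per-marker allele frequencies
    drawn uniformly in [maf_low, maf_high]."""
    if n_founders <= 0:
        raise ValueError("n_founders must be positive")
    if not 0.0 < maf_low <= maf_high <= 0.5:
        raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
    rng = np.random.default_rng(seed)
    m = map.n_markers
    freq = rng.uniform(maf_low, maf_high, size=m)
    calls = (rng.random((n_founders, m)) < freq).astype(np.int8) * 2
    ids, chrom, bp, cm = map.marker_metadata()
    founder_ids = [_founder_name(i) for i in range(n_founders)]
    return GenotypeMatrix(calls, founder_ids, ids, chrom, bp, pos_cm=cm)


def _founder_name(i: int) -> str:
    name = ""
    i0 = i
    while True:
        name = chr(ord("A") + i0 % 26) + name
        i0 = i0 // 26 - 1
        if i0 < 0:
            return name


def _gamete(rng: np.random.Generator, hap0: np.ndarray, hap1: np.ndarray,
            cm: np.ndarray) -> np.ndarray:
    """One recombinant gamete from a pair of chromosome haplotypes.

    Crossover count ~ Poisson(length/100 cM), positions uniform on the cM
    scale, no interference.
    """
    length = cm[-1] - cm[0] if len(cm) > 1 else 0.0
    n_co = rng.poisson(length / 100.0)
    start = int(rng.integers(2))
    if n_co == 0:
        return (hap0 if start == 0 else hap1).copy()
    xs = np.sort(rng.uniform(cm[0], cm[-1], size=n_co))
    seg = start + np.searchsorted(xs, cm, side="right")
    return np.where(seg % 2 == 0, hap0, hap1)


def simulate_dh_population(
    founders: GenotypeMatrix, plan: CrossPlan, map: GeneticMap, seed: int = 0,
) -> tuple[GenotypeMatrix, Pedigree]:
    """DH lines from each planned (back)cross: a doubled gamete of the F1
    (or BC1) individual, hence fully homozygous."""
    if np.any(founders.calls == 1):
        raise ValueError("founders must be homozygous")
    rng = np.random.default_rng(seed)
    fidx = {name: i for i, name in enumerate(founders.line_ids)}
    for p1, p2, bc, _ in plan.families:
        for p in (p1, p2) + (() if bc is None else (bc,)):
            if p not in fidx:
                raise ValueError(f"unknown parent id {p!r}")

    chrom_bounds = []
    off = 0
    for _, cm, _ in map.chromosomes:
        chrom_bounds.append((off, off + len(cm), np.asarray(cm, float)))
        off += len(cm)

    lines, line_ids = [], []
    ped = Pedigree()
    for name in founders.line_ids:
        ped.add(name, None, None, "founder")
    for fam_i, (p1, p2, bc, size) in enumerate(plan.families):
        # founder haplotypes (homozygous: one haplotype each, coded 0/1 allele dose)
        h1 = (founders.calls[fidx[p1]] // 2).astype(np.int8)
        h2 = (founders.calls[fidx[p2]] // 2).astype(np.int8)
        f1_id = f"F1_{p1}{p2}"
        if f1_id not in ped:
            ped.add(f1_id, p1, p2, "cross")
        if bc is not None:
            source_id = f"BC_{p1}{p2}x{bc}"
            hb = (founders.calls[fidx[bc]] // 2).astype(np.int8)
        else:
            source_id = f1_id
        bc_registered = False
        for k in range(size):
            dh = np.empty(founders.n_markers, dtype=np.int8)
            for lo, hi, cm in chrom_bounds:
                if bc is not None:
                    # gamete of the BC1 individual: one F1 gamete paired with
                    # the recurrent parent's chromosome, then recombined
                    f1_gam = _gamete(rng, h1[lo:hi], h2[lo:hi], cm)
                    gam = _gamete(rng, f1_gam, hb[lo:hi], cm)
                else:
                    gam = _gamete(rng, h1[lo:hi], h2[lo:hi], cm)
                dh[lo:hi] = gam * 2  # doubled gamete
            if bc is not None and not bc_registered:
                ped.add(source_id, f1_id, bc, "backcross")
                bc_registered = True
            lid = f"DH{fam_i + 1:02d}_{k + 1:03d}"
            parents = (f1_id, bc) if bc is not None else (p1, p2)
            ped.add(lid, parents[0], parents[1], "dh")
            lines.append(dh)
            line_ids.append(lid)
    geno = GenotypeMatrix(
        np.vstack(lines), line_ids, founders.marker_ids, founders.chrom,
        founders.pos_bp, pos_cm=founders.pos_cm,
    )
    return geno, ped


def apply_gbs_missingness(
    geno: GenotypeMatrix, coverage: float = 1.0, seed: int = 0,
    marker_dispersion: float = 0.0, het_error_rate: float = 0.0,
) -> GenotypeMatrix:
    """Mask each call independently with the zero-read probability
    exp(-coverage) of a Poisson read-count model.

    ``marker_dispersion`` > 0 draws a lognormal per-marker coverage
    multiplier (sequencing depth varies along the genome); the default is
    the plain homogeneous Poisson expectation.  ``het_error_rate`` > 0 flips
    called genotypes to a spurious heterozygote at that rate, emulating
    sequencing error on inbred material.
    """
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    rng = np.random.default_rng(seed)
    n, m = geno.calls.shape
    if marker_dispersion > 0:
        mult = rng.lognormal(-0.5 * marker_dispersion ** 2, marker_dispersion, size=m)
        p_miss = np.exp(-coverage * mult)[None, :]
    else:
        p_miss = np.exp(-coverage)
    out = geno.copy()
    mask = rng.random((n, m)) < p_miss
    out.calls[mask] = MISSING
    if het_error_rate > 0:
        flip = (rng.random((n, m)) < het_error_rate) & (out.calls != MISSING)
        out.calls[flip] = 1
    return out


def simulate_phenotypes(
    geno: GenotypeMatrix, params: PhenotypeParams, seed: int = 0,
    qtl_indices: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Plot-level phenotypes y(line, env, rep) = mu + env + block + g + ge + e.

    Genetic values g are additive over ``n_qtl`` markers drawn at random
    (or the given ``qtl_indices``), rescaled so var(g) = sigma_g2.  Returns
    the long-format plot table and the true breeding values (for oracle
    tests).
    """
    if params.n_qtl > geno.n_markers:
        raise ValueError("n_qtl exceeds marker count")
    rng = np.random.default_rng(seed)
    n = geno.n_lines
    if qtl_indices is None:
        qtl = rng.choice(geno.n_markers, size=params.n_qtl, replace=False)
    else:
        qtl = np.asarray(qtl_indices)
    X = geno.calls[:, qtl].astype(float)
    X[X == MISSING] = np.nan
    col_mean = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), col_mean[None, :], X) - col_mean[None, :]
    beta = rng.normal(size=params.n_qtl)
    g = X @ beta
    sd = g.std()
    if params.sigma_g2 > 0 and sd > 0:
        g = g / sd * np.sqrt(params.sigma_g2)
    else:
        g = np.zeros(n)
    g = g - g.mean()

    env_eff = rng.normal(0.0, params.env_sd, size=params.n_env)
    ge = rng.normal(0.0, np.sqrt(params.sigma_ge2), size=(n, params.n_env)) \
        if params.sigma_ge2 > 0 else np.zeros((n, params.n_env))

    rows = []
    n_blocks = max(1, int(np.ceil(n / params.block_size)))
    for e in range(params.n_env):
        for r in range(params.n_rep):
            order = rng.permutation(n)
            block_of = np.empty(n, dtype=int)
            block_of[order] = np.arange(n) // params.block_size
            b_eff = rng.normal(0.0, params.block_sd, size=n_blocks) \
                if params.block_sd > 0 else np.zeros(n_blocks)
            eps = rng.normal(0.0, np.sqrt(params.sigma_e2), size=n) \
                if params.sigma_e2 > 0 else np.zeros(n)
            for i, line in enumerate(geno.line_ids):
                rows.append((
                    line, f"env{e + 1}", r + 1, f"env{e + 1}_r{r + 1}_b{block_of[i] + 1}",
                    params.mu + env_eff[e] + b_eff[block_of[i]] + g[i] + ge[i, e] + eps[i],
                ))
    plots = pd.DataFrame(rows, columns=["line", "env", "rep", "block", "value"])
    tbv = pd.Series(g, index=geno.line_ids, name="tbv")
    return plots, tbv


def simulate_study(
    n_lines: int = 300, n_chrom: int = 2, markers_per_chrom: int = 2000,
    coverage: float = 1.0, pheno: PhenotypeParams | None = None,
    maf_low: float = 0.1, maf_high: float = 0.5,
    exclude_qtl_from_panel: bool = True, seed: int = 0,
):
    """End-to-end convenience generator: founders -> DH families -> GBS
    missingness -> phenotypes.  Returns (true_geno, observed_geno, pedigree,
    plots, tbv).

    By default the causal QTL are *excluded* from the genotyping panel
    (``observed_geno``): called SNPs tag causal variants only through
    linkage, as with real reduced-representation sequencing where the causal
    polymorphisms are generally not among the called sites.  ``true_geno``
    always carries every simulated locus.
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=5)
    gmap = GeneticMap.uniform(n_chrom, markers_per_chrom)
    plan = CrossPlan.default_study(scale=n_lines / 504.0)
    founders = simulate_founders(8, gmap, maf_low, maf_high, seed=int(seeds[0]))
    geno, ped = simulate_dh_population(founders, plan, gmap, seed=int(seeds[1]))
    pheno = pheno or PhenotypeParams()
    if pheno.n_qtl > geno.n_markers // 2:
        # small maps cannot host the default architecture; cap so the panel
        # keeps at least half the loci
        pheno = dataclasses.replace(pheno, n_qtl=geno.n_markers // 2)
    qtl = np.random.default_rng(int(seeds[4])).choice(
        geno.n_markers, size=pheno.n_qtl, replace=False)
    plots, tbv = simulate_phenotypes(geno, pheno, seed=int(seeds[3]),
                                     qtl_indices=qtl)
    panel = geno
    if exclude_qtl_from_panel:
        keep = np.setdiff1d(np.arange(geno.n_markers), qtl)
        panel = geno.take_markers(keep)
    obs = apply_gbs_missingness(panel, coverage=coverage, seed=int(seeds[2]))
    return geno, obs, ped, plots, tbv
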