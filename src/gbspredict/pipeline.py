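"""Config-driven end-to-end runner.

simulate (or load) -> marker edit -> haplotype imputation variants ->
kernel construction (with or without pedigree) -> Bayesian GBLUP/RKHS ->
replicated cross validation -> report tables.

Model labels follow the field's notation grammar::

    P                      pedigree only
    {P}?GBLUP{suffix}      genomic BLUP, optionally with the pedigree kernel
    {P}?RKHS{suffix}       RKHS kernel averaging, ditto

with suffix '' (nonimputed GBS), _IM (imputed, 1000-marker flank), _H
(haplotype alleles, 1000-marker flank), _IMS/_HS (50) and _IML/_HL (100).

All randomness derives from one master seed via named child seeds, so any
stage can be re-run in isolation and reproduce its outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
import re
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bayes, evaluation, relmat, simgbs
from .genotype import (GenotypeMatrix, expected_value_impute, filter_markers,
                       read_genotypes, set_heterozygotes_missing)
from .impute import HaplotypeImputer
from .pedigree import Pedigree

log = logging.getLogger("gbspredict")

_LABEL_RE = re.compile(r"^(P?)(GBLUP|RKHS)(?:_(IM|H|IMS|IML|HS|HL))?$")
_FLANK = {"IM": 1000, "H": 1000, "IMS": 50, "HS": 50, "IML": 100, "HL": 100}


@dataclasses.dataclass
class LabelSpec:
    label: str
    pedigree: bool
    method: str | None  # None for the bare pedigree model
    source: str | None  # None = nonimputed; IM*/H* otherwise

    @property
    def flank(self) -> int | None:
        return _FLANK.get(self.source) if self.source else None

    @property
    def uses_haplotypes(self) -> bool:
        return self.source is not None and self.source.startswith("H")


def parse_label(label: str) -> LabelSpec:
    if label == "P":
        return LabelSpec(label, True, None, None)
    m = _LABEL_RE.match(label)
    if not m:
        raise ValueError(f"model label {label!r} not in the notation grammar")
    return LabelSpec(label, m.group(1) == "P", m.group(2), m.group(3))


def format_label(spec: LabelSpec) -> str:
    if spec.method is None:
        return "P"
    return ("P" if spec.pedigree else "") + spec.method + \
        (f"_{spec.source}" if spec.source else "")


def child_seed(master: int, name: str) -> int:
    """Deterministic per-stage seed: crc32 of the stage name folded into
    the master seed, kept below 2**31."""
    return (master * 1_000_003 + zlib.crc32(name.encode())) % (2**31 - 1)


@dataclasses.dataclass
class RunConfig:
    # simulation (ignored when genotype/pedigree/phenotype paths are given)
    n_lines: int = 300
    n_chrom: int = 2
    markers_per_chrom: int = 500
    coverage: float = 1.0
    pheno: dict = dataclasses.field(default_factory=dict)
    genotypes: str | None = None
    pedigree: str | None = None
    phenotypes: str | None = None
    # marker edit
    max_missing: float = 0.80
    min_maf: float = 0.05
    # models and evaluation
    models: list[str] = dataclasses.field(
        default_factory=lambda: ["P", "GBLUP", "PGBLUP", "RKHS", "PRKHS"])
    bandwidths: list[float] = dataclasses.field(
        default_factory=lambda: list(relmat.DEFAULT_BANDWIDTHS))
    incidence_stride: int = 1
    mcmc: dict = dataclasses.field(default_factory=dict)
    n_partitions: int = 50
    train_fraction: float = 0.7
    ld_max_distance_bp: int = 2_000_000
    # bookkeeping
    outdir: str = "run"
    seed: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def mcmc_config(self) -> bayes.MCMCConfig:
        return bayes.MCMCConfig(seed=child_seed(self.seed, "mcmc"), **self.mcmc)


def _setup_logging(outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s",
                            datefmt="%Y-%m-%dT%H:%M:%S")
    fh = logging.FileHandler(outdir / "run.log")
    fh.setFormatter(fmt)
    log.setLevel(logging.INFO)
    log.addHandler(fh)


def stage_simulate(cfg: RunConfig):
    """Simulate (or load) genotypes, pedigree and phenotypes."""
    if cfg.genotypes:
        geno = read_genotypes(cfg.genotypes)
        ped = Pedigree.read_csv(cfg.pedigree) if cfg.pedigree else None
        plots = pd.read_csv(cfg.phenotypes) if cfg.phenotypes else None
        return geno, ped, plots, None
    pheno = simgbs.PhenotypeParams(**cfg.pheno)
    _, obs, ped, plots, tbv = simgbs.simulate_study(
        n_lines=cfg.n_lines, n_chrom=cfg.n_chrom,
        markers_per_chrom=cfg.markers_per_chrom, coverage=cfg.coverage,
        pheno=pheno, seed=child_seed(cfg.seed, "simulate"),
    )
    log.info("simulated %d lines x %d markers, %.1f%% missing",
             obs.n_lines, obs.n_markers, 100 * obs.missing_fraction())
    return obs, ped, plots, tbv


def stage_edit(cfg: RunConfig, geno: GenotypeMatrix):
    """Heterozygote masking and the missingness/MAF marker filter."""
    masked = set_heterozygotes_missing(geno)
    filtered, report = filter_markers(masked, cfg.max_missing, cfg.min_maf)
    log.info("marker edit: %d -> %d markers", geno.n_markers, filtered.n_markers)
    return filtered, report


def _needed_flanks(labels: list[LabelSpec]) -> set[int]:
    return {s.flank for s in labels if s.flank is not None}


def stage_impute(cfg: RunConfig, geno: GenotypeMatrix, labels: list[LabelSpec]):
    """Run the haplotype imputer once per required flank size."""
    imputers: dict[int, HaplotypeImputer] = {}
    for flank in sorted(_needed_flanks(labels)):
        imp = HaplotypeImputer(flank_size=flank, stride=cfg.incidence_stride)
        imp.fit(geno)
        imputers[flank] = imp
        log.info("imputation flank=%d: %d cells imputed", flank, imp.n_imputed_)
    return imputers


def stage_kernels(cfg: RunConfig, geno: GenotypeMatrix,
                  ped: Pedigree | None, labels: list[LabelSpec],
                  imputers: dict[int, "HaplotypeImputer"]) -> list[bayes.ModelSpec]:
    """Build each model's kernel set from its label."""
    A = relmat.a_matrix(ped, geno.line_ids) if ped is not None else None
    X_ni = geno.calls.astype(float)
    X_ni[geno.missing_mask] = np.nan

    def source_matrix(spec: LabelSpec):
        if spec.source is None:
            return X_ni, False
        imp = imputers[spec.flank]
        if spec.uses_haplotypes:
            H, _ = imp.haplotype_incidence()
            return H.astype(float), True
        return expected_value_impute(imp.imputed_.geno), False

    specs = []
    for spec in labels:
        kernels: relmat.KernelSet = {}
        if spec.pedigree:
            if A is None:
                raise ValueError(f"model {spec.label} needs a pedigree")
            kernels["A"] = A
        if spec.method == "GBLUP":
            X, is_hap = source_matrix(spec)
            kernels["G"] = relmat.grm_from_haplotypes(X) if is_hap \
                else relmat.grm_from_markers(X)
        elif spec.method == "RKHS":
            X, is_hap = source_matrix(spec)
            kernels.update(relmat.gaussian_kernels(
                X, tuple(cfg.bandwidths), scale_to_unit=not is_hap))
        specs.append(bayes.ModelSpec(kernels, spec.label))
    return specs


def stage_cv(cfg: RunConfig, y: pd.Series, specs: list[bayes.ModelSpec]):
    parts = evaluation.make_partitions(
        len(y), cfg.train_fraction, cfg.n_partitions,
        seed=child_seed(cfg.seed, "cv"))
    return evaluation.run_cv(y.to_numpy(), specs, parts, cfg.mcmc_config())


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute every stage; returns the run directory."""
    outdir = Path(cfg.outdir)
    _setup_logging(outdir)
    log.info("run started %s, master seed %d",
             datetime.datetime.now().isoformat(timespec="seconds"), cfg.seed)
    labels = [parse_label(l) for l in cfg.models]

    try:
        geno, ped, plots, tbv = stage_simulate(cfg)
        filtered, edit_report = stage_edit(cfg, geno)
        edit_report.to_csv(outdir / "marker_edit.csv")

        imputers = stage_impute(cfg, filtered, labels)
        for flank, imp in imputers.items():
            imp.imputed_.missing_summary().to_csv(
                outdir / f"imputation_flank{flank}.csv", index=False)

        y = evaluation.adjust_phenotypes(plots).reindex(filtered.line_ids)
        vc = evaluation.anova_varcomp(plots)
        h2 = evaluation.heritability(vc)
        pd.DataFrame([{
            "sigma_g2": vc.sigma_g2, "sigma_ge2": vc.sigma_ge2,
            "sigma_e2": vc.sigma_e2, "n_env": vc.n_env, "n_rep": vc.n_rep,
            "heritability": round(h2, 3),
        }]).to_csv(outdir / "heritability.csv", index=False)
        log.info("broad-sense heritability %.3f", h2)

        specs = stage_kernels(cfg, filtered, ped, labels, imputers)
        for spec in specs:
            for name, K in spec.kernels.items():
                pd.DataFrame(K.values, index=filtered.line_ids,
                             columns=filtered.line_ids).to_csv(
                    outdir / f"kernel_{spec.label}_{name}.csv")

        cv = stage_cv(cfg, y, specs)
        cv.correlations.to_csv(outdir / "cv_correlations.csv", index=False)
        baseline = "P" if any(s.label == "P" for s in specs) else None
        table = cv.summary(baseline)
        table.to_csv(outdir / "cv_table.csv", index=False)
        log.info("cv table:\n%s", table.to_string(index=False))

        _, binned = evaluation.ld_r2(filtered, cfg.ld_max_distance_bp)
        binned.to_csv(outdir / "ld_binned.csv", index=False)
    except Exception:
        log.exception("pipeline stage failed")
        raise
    log.info("run finished")
    return outdir
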