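"""Phenotype adjustment, variance components, cross-validated prediction
accuracy and LD summaries.

The evaluation pipeline mirrors standard plant-breeding practice: plot
values from a replicated incomplete-block trial are pre-adjusted for
environment and block effects; line-level means feed the prediction models;
predictive ability is the Pearson correlation between predicted and
observed values in each of many random 70/30 training/testing partitions,
reported as mean (SD over partitions) and as percent change against a
baseline model (conventionally the pedigree model).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .bayes import MCMCConfig, ModelSpec, fit as _fit_model
from .genotype import MISSING, GenotypeMatrix

PLOT_COLUMNS = ("line", "env", "rep", "block", "value")


@dataclasses.dataclass
class VarianceComponents:
    """Genotype, GxE and error variance components with the trial layout."""

    sigma_g2: float
    sigma_ge2: float
    sigma_e2: float
    n_env: int
    n_rep: int

    def __post_init__(self) -> None:
        if self.n_env < 1 or self.n_rep < 1:
            raise ValueError("need e >= 1 and r >= 1")
        self.sigma_g2 = max(0.0, self.sigma_g2)
        self.sigma_ge2 = max(0.0, self.sigma_ge2)
        self.sigma_e2 = max(0.0, self.sigma_e2)


@dataclasses.dataclass
class CVPartition:
    replicate: int
    train: np.ndarray
    test: np.ndarray


@dataclasses.dataclass
class CVResult:
    """Per-(model, replicate) predictive correlations with summaries."""

    correlations: pd.DataFrame  # columns: label, replicate, corr

    def summary(self, baseline: str | None = None) -> pd.DataFrame:
        g = self.correlations.groupby("label", sort=False)["corr"]
        out = pd.DataFrame({"mean_corr": g.mean().round(3), "sd_corr": g.std(ddof=1).round(3)})
        if baseline is not None:
            base = out.loc[baseline, "mean_corr"]
            out["pct_change_vs_" + baseline] = [
                percent_change(m, base) for m in out["mean_corr"]
            ]
        return out.reset_index()


def heritability(vc: VarianceComponents) -> float:
    """Broad-sense heritability on an entry-mean basis:
    h2 = sg2 / (sg2 + sge2/e + se2/(e*r))."""
    denom = vc.sigma_g2 + vc.sigma_ge2 / vc.n_env + vc.sigma_e2 / (vc.n_env * vc.n_rep)
    if denom <= 0:
        raise ValueError("all variance components are zero")
    return vc.sigma_g2 / denom


def percent_change(model_corr: float, baseline_corr: float) -> float:
    """100 x (model - baseline)/baseline, to one decimal as reported."""
    if baseline_corr == 0:
        raise ZeroDivisionError("baseline correlation is zero")
    return round(100.0 * (model_corr - baseline_corr) / baseline_corr, 1)


# ---------------------------------------------------------------------------
# phenotype pre-adjustment
# ---------------------------------------------------------------------------

def _check_plots(plots: pd.DataFrame) -> None:
    missing = [c for c in PLOT_COLUMNS if c not in plots.columns]
    if missing:
        raise ValueError(f"plot table lacks columns {missing}")


def _check_connected(plots: pd.DataFrame) -> None:
    """Lines and blocks must form one connected bipartite design."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    lines = pd.Categorical(plots["line"])
    blocks = pd.Categorical(plots["block"])
    nl, nb = len(lines.categories), len(blocks.categories)
    adj = coo_matrix(
        (np.ones(len(plots)),
         (lines.codes.astype(np.int64), blocks.codes.astype(np.int64) + nl)),
        shape=(nl + nb, nl + nb),
    )
    adj = adj + adj.T
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        main = np.bincount(labels).argmax()
        orphans = [blocks.categories[i] for i in range(nb)
                   if labels[nl + i] != main]
        raise ValueError(f"disconnected trial design; orphan blocks: {orphans[:10]}")


def adjust_phenotypes(plots: pd.DataFrame) -> pd.Series:
    """Remove least-squares environment and block-within-(env, rep) effects
    from plot values; returns adjusted line means indexed by line.

    The adjustment model is value ~ env + block(env, rep) + line, fitted by
    OLS with treatment coding, so that line effects do not leak into the
    block estimates; only the environment and block estimates are
    subtracted from the plot values.
    """
    _check_plots(plots)
    _check_connected(plots)
    y = plots["value"].to_numpy(float)
    env = pd.get_dummies(plots["env"], drop_first=True, dtype=float)
    cell = plots["env"].astype(str) + "/" + plots["rep"].astype(str)
    # drop one block per (env, rep) cell to avoid collinearity with env
    block_lab = cell + "/" + plots["block"].astype(str)
    drop = set(plots.assign(_b=block_lab).groupby(cell)["_b"].first())
    block = pd.get_dummies(block_lab, dtype=float).drop(columns=list(drop))
    line = pd.get_dummies(plots["line"], drop_first=True, dtype=float)
    X = np.column_stack([np.ones(len(y)), env.to_numpy(), block.to_numpy(),
                         line.to_numpy()])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    n_env, n_block = env.shape[1], block.shape[1]
    nuisance = (env.to_numpy() @ beta[1:1 + n_env]
                + block.to_numpy() @ beta[1 + n_env:1 + n_env + n_block])
    adjusted = pd.Series(y - nuisance, index=plots["line"].to_numpy())
    return adjusted.groupby(level=0, sort=False).mean()


# ---------------------------------------------------------------------------
# variance components
# ---------------------------------------------------------------------------

def anova_varcomp(plots: pd.DataFrame) -> VarianceComponents:
    """Method-of-moments variance components from the balanced two-way
    (line x env, r reps) ANOVA; negative estimates truncate to zero."""
    _check_plots(plots)
    counts = plots.groupby(["line", "env"], observed=True)["value"].count()
    r_set = set(counts)
    if len(r_set) != 1:
        raise ValueError(
            "unbalanced layout: every line x env cell needs the same number "
            "of replicates (adjust or balance the table first)")
    r = r_set.pop()
    wide = plots.groupby(["line", "env"], observed=True)["value"].mean().unstack()
    if wide.isna().any().any():
        raise ValueError("unbalanced layout: missing line x env cells")
    g, e = wide.shape
    cell = wide.to_numpy()
    line_mean = cell.mean(axis=1)
    env_mean = cell.mean(axis=0)
    grand = cell.mean()

    cell_mean_per_plot = plots.groupby(["line", "env"], observed=True)["value"] \
        .transform("mean")
    ss_error = float(((plots["value"] - cell_mean_per_plot) ** 2).sum())
    df_error = g * e * (r - 1)
    ms_error = ss_error / df_error if df_error > 0 else 0.0
    ss_ge = r * float(((cell - line_mean[:, None] - env_mean[None, :] + grand) ** 2).sum())
    ms_ge = ss_ge / ((g - 1) * (e - 1))
    ss_g = e * r * float(((line_mean - grand) ** 2).sum())
    ms_g = ss_g / (g - 1)

    return VarianceComponents(
        sigma_g2=(ms_g - ms_ge) / (e * r),
        sigma_ge2=(ms_ge - ms_error) / r,
        sigma_e2=ms_error,
        n_env=e, n_rep=r,
    )


# ---------------------------------------------------------------------------
# cross validation
# ---------------------------------------------------------------------------

def make_partitions(n_lines: int, train_fraction: float = 0.7,
                    n_replicates: int = 50, seed: int = 0) -> list[CVPartition]:
    """Independent uniform random 70/30 training/testing splits."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0,1)")
    if n_lines < 10:
        raise ValueError("need at least 10 lines for cross validation")
    rng = np.random.default_rng(seed)
    n_train = int(round(train_fraction * n_lines))
    parts = []
    for rep in range(n_replicates):
        perm = rng.permutation(n_lines)
        parts.append(CVPartition(rep, np.sort(perm[:n_train]),
                                 np.sort(perm[n_train:])))
    return parts


def run_cv(y, model_specs: list[ModelSpec], partitions: list[CVPartition],
           mcmc: MCMCConfig | None = None) -> CVResult:
    """Fit each model on every training partition and correlate predictions
    with the observed values of the held-out lines."""
    y = np.asarray(y, float)
    mcmc = mcmc or MCMCConfig()
    labels = [s.label for s in model_specs]
    if len(set(labels)) != len(labels):
        raise ValueError("model labels must be unique within a run")
    rows = []
    for spec in model_specs:
        for part in partitions:
            y_masked = y.copy()
            y_masked[part.test] = np.nan
            cfg = dataclasses.replace(mcmc, seed=mcmc.seed + 7919 * part.replicate)
            summary = _fit_model(y_masked, spec, cfg)
            pred = summary.genetic_values[part.test]
            obs = y[part.test]
            if np.std(pred) == 0 or np.std(obs) == 0:
                warnings.warn(
                    f"constant predictions for {spec.label} rep {part.replicate}")
                corr = np.nan
            else:
                corr = float(np.corrcoef(pred, obs)[0, 1])
            rows.append({"label": spec.label, "replicate": part.replicate,
                         "corr": corr})
    return CVResult(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def ld_r2(geno: GenotypeMatrix, max_distance_bp: int = 1_000_000,
          n_bins: int = 10) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise r^2 (squared Pearson correlation of allele counts, on
    pairwise-complete lines) between loci within ``max_distance_bp`` on the
    same chromosome, with binned distance medians.

    Returns (pairs, binned) where pairs has columns chrom, pos1, pos2,
    distance, r2 and binned has bin midpoints and median r2.  Monomorphic
    loci are skipped (counted in pairs.attrs['n_monomorphic']).
    """
    X = geno.calls.astype(float)
    X[geno.calls == MISSING] = np.nan
    rows = []
    n_mono = 0
    for c, idx in geno.chromosome_slices().items():
        pos = geno.pos_bp[idx]
        Xc = X[:, idx]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            var = np.nanvar(Xc, axis=0)
        poly = var > 0
        n_mono += int((~poly).sum())
        for a in range(len(idx)):
            if not poly[a]:
                continue
            upper = np.searchsorted(pos, pos[a] + max_distance_bp, side="right")
            for b in range(a + 1, upper):
                if not poly[b]:
                    continue
                xa, xb = Xc[:, a], Xc[:, b]
                ok = ~np.isnan(xa) & ~np.isnan(xb)
                if ok.sum() < 2:
                    continue
                va, vb = xa[ok], xb[ok]
                if va.std() == 0 or vb.std() == 0:
                    continue
                r = np.corrcoef(va, vb)[0, 1]
                rows.append((c, int(pos[a]), int(pos[b]),
                             int(pos[b] - pos[a]), r * r))
    pairs = pd.DataFrame(rows, columns=["chrom", "pos1", "pos2", "distance", "r2"])
    pairs.attrs["n_monomorphic"] = n_mono
    if len(pairs):
        edges = np.linspace(0, max_distance_bp, n_bins + 1)
        pairs["bin"] = pd.cut(pairs["distance"], edges, include_lowest=True)
        binned = pairs.groupby("bin", observed=True)["r2"].median().reset_index()
        binned["bin_mid"] = [iv.mid for iv in binned["bin"]]
        pairs = pairs.drop(columns="bin")
    else:
        binned = pd.DataFrame(columns=["bin", "r2", "bin_mid"])
    return pairs, binned
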