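"""Bayesian kernel regression: GBLUP and RKHS kernel averaging by Gibbs
sampling.

Model: y = 1 mu + sum_k u_k + e, with u_k ~ N(0, sigma2_k K_k) for each
kernel in the set (a pedigree A, a genomic G, or several Gaussian kernels —
one variance per kernel implements kernel averaging) and
e ~ N(0, sigma2_e I).  Variances carry scaled-inverse-chi-square priors.
Each kernel is eigendecomposed once and u_k is sampled in its eigenbasis,
so one Gibbs iteration costs a couple of matrix-vector products per kernel.
Phenotypes of test lines are treated as unknowns and sampled within the
chain, which makes prediction the posterior mean of mu + sum_k u_k at
those lines and keeps a single code path for training and prediction.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .relmat import KernelSet, RelationshipMatrix


@dataclasses.dataclass
class MCMCConfig:
    """Chain length, burn-in, thinning, seed and variance priors."""

    n_iter: int = 6000
    burn_in: int = 1000
    thin: int = 5
    seed: int = 0
    prior_df: float = 5.0
    prior_scale_fraction: float | None = None  # default 0.5 / n_kernels

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclasses.dataclass
class ModelSpec:
    """Named kernel set entering one model (e.g. {'A': ..., 'G': ...})."""

    kernels: KernelSet
    label: str = "model"

    def __post_init__(self) -> None:
        if len(self.kernels) < 1:
            raise ValueError("ModelSpec needs at least one kernel")
        dims = {k.n for k in self.kernels.values()}
        if len(dims) > 1:
            raise ValueError("kernel dimensions differ")


@dataclasses.dataclass
class PosteriorSummary:
    """Posterior means/SDs of the model unknowns plus per-line values."""

    label: str
    mu: float
    mu_sd: float
    var_kernel: dict[str, float]
    var_kernel_sd: dict[str, float]
    var_resid: float
    var_resid_sd: float
    u: dict[str, np.ndarray]  # posterior mean genetic values per kernel
    genetic_values: np.ndarray  # mu + sum_k u_k
    yhat: np.ndarray  # posterior mean of sampled y (equals genetic_values)
    n_samples: int
    kernel_scale: dict[str, float] | None = None  # tr(PKP)/(n-1) per kernel
    line_ids: list[str] | None = None
    trace: "object | None" = None  # per-sample scalar draws (DataFrame)

    def heritability(self) -> float:
        """Trait-scale genomic heritability: the variance a kernel
        contributes among lines is sigma2_k * tr(PKP)/(n-1) (P the centering
        projector), which corrects for kernel scale (e.g. VanRaden G has
        diagonal ~2 for fully inbred lines)."""
        if not self.kernel_scale:
            raise ValueError("kernel scales unavailable")
        vg = sum(self.var_kernel[k] * self.kernel_scale[k] for k in self.var_kernel)
        return vg / (vg + self.var_resid)

    def predict(self, test_lines) -> np.ndarray:
        """Predicted genetic values mu + sum_k u_k for the given lines
        (integer indices, or ids when line_ids are attached)."""
        idx = _resolve_lines(test_lines, self.line_ids, len(self.genetic_values))
        return self.genetic_values[idx]

    def to_csv(self, path: str | Path) -> None:
        """Per-line posterior mean genetic values (one column per kernel)."""
        import pandas as pd

        idx = self.line_ids or list(range(len(self.genetic_values)))
        df = pd.DataFrame({f"u_{k}": v for k, v in self.u.items()}, index=idx)
        df["genetic_value"] = self.genetic_values
        df.to_csv(path, index_label="line")

    def trace_to_csv(self, path: str | Path) -> None:
        if self.trace is None:
            raise ValueError("chain trace was not recorded (keep_trace=False)")
        self.trace.to_csv(path, index_label="sample")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "label": self.label, "mu": self.mu, "mu_sd": self.mu_sd,
            "var_kernel": self.var_kernel, "var_kernel_sd": self.var_kernel_sd,
            "var_resid": self.var_resid, "var_resid_sd": self.var_resid_sd,
            "n_samples": self.n_samples,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _resolve_lines(test_lines, line_ids, n) -> np.ndarray:
    arr = np.asarray(test_lines)
    if arr.dtype.kind in "iu":
        if arr.max(initial=-1) >= n:
            raise KeyError(f"line index out of range (n={n})")
        return arr
    if line_ids is None:
        raise KeyError("no line ids attached; pass integer indices")
    lookup = {l: i for i, l in enumerate(line_ids)}
    try:
        return np.array([lookup[l] for l in arr])
    except KeyError as e:
        raise KeyError(f"unknown line id {e.args[0]!r}") from None


class KernelBayesRegressor(BaseEstimator, RegressorMixin):
    """Multi-kernel Bayesian mixed model (GBLUP / RKHS kernel averaging).

    Parameters
    ----------
    n_iter, burn_in, thin, seed, prior_df, prior_scale_fraction
        MCMC configuration (see :class:`MCMCConfig`).
    fixed_variances : dict or None
        Optional {'kernel name': value, ..., 'resid': value} to clamp
        variance components (used for closed-form validation).

    ``fit(kernels, y)`` takes the kernel set over the *full* line set and a
    response with NaN at lines to be predicted.  Fitted attributes follow
    scikit-learn conventions (``mu_``, ``u_``, ``var_kernel_``,
    ``genetic_values_``, ``summary_``).
    """

    def __init__(self, n_iter: int = 6000, burn_in: int = 1000, thin: int = 5,
                 seed: int = 0, prior_df: float = 5.0,
                 prior_scale_fraction: float | None = None,
                 fixed_variances: dict | None = None, label: str = "model",
                 keep_trace: bool = False):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.prior_df = prior_df
        self.prior_scale_fraction = prior_scale_fraction
        self.fixed_variances = fixed_variances
        self.label = label
        self.keep_trace = keep_trace

    # -- internals ----------------------------------------------------------
    def _eigendecompose(self, kernels: KernelSet):
        eig = {}
        for name, K in kernels.items():
            vals, vecs = np.linalg.eigh(K.values)
            if vals[0] < -1e-6:
                raise ValueError(
                    f"kernel {name!r} is not PSD (min eigenvalue {vals[0]:.3g})")
            keep = vals > 1e-10
            eig[name] = (vals[keep], vecs[:, keep])
        return eig

    def fit(self, kernels: KernelSet | ModelSpec, y) -> "KernelBayesRegressor":
        if isinstance(kernels, ModelSpec):
            self.label = kernels.label
            kernels = kernels.kernels
        if isinstance(kernels, (RelationshipMatrix, np.ndarray)):
            k = kernels if isinstance(kernels, RelationshipMatrix) \
                else RelationshipMatrix(np.asarray(kernels, float), "genomic-G")
            kernels = {"K": k}
        y = np.asarray(y, float)
        n = len(y)
        for name, K in kernels.items():
            if K.n != n:
                raise ValueError(f"kernel {name!r} dimension {K.n} != len(y) {n}")
        obs = ~np.isnan(y)
        if obs.sum() < 2:
            raise ValueError("need at least 2 observed phenotypes")
        cfg = MCMCConfig(self.n_iter, self.burn_in, self.thin, self.seed,
                         self.prior_df, self.prior_scale_fraction)
        eig = self._eigendecompose(kernels)
        self.summary_ = _gibbs(y, obs, eig, cfg, self.fixed_variances, self.label,
                               keep_trace=self.keep_trace)
        self.mu_ = self.summary_.mu
        self.u_ = self.summary_.u
        self.var_kernel_ = self.summary_.var_kernel
        self.var_resid_ = self.summary_.var_resid
        self.genetic_values_ = self.summary_.genetic_values
        return self

    def predict(self, test_lines=None) -> np.ndarray:
        if not hasattr(self, "summary_"):
            raise ValueError("KernelBayesRegressor is not fitted")
        if test_lines is None:
            return self.genetic_values_
        return self.summary_.predict(test_lines)


def _gibbs(y, obs, eig, cfg: MCMCConfig, fixed, label,
           keep_trace: bool = False) -> PosteriorSummary:
    rng = np.random.default_rng(cfg.seed)
    n = len(y)
    names = list(eig)
    nk = len(names)
    vy = float(np.var(y[obs]))
    if vy <= 0:
        vy = 1.0
    frac = cfg.prior_scale_fraction
    if frac is None:
        frac = 0.5 / nk
    nu = cfg.prior_df
    # kernel scale: variance contributed among lines per unit sigma2_k is
    # c_k = tr(PKP)/(n-1); priors refer to trait-scale genetic variance
    c_k = {}
    for nm in names:
        d, V = eig[nm]
        v1 = V.T @ np.ones(n)
        c = (d.sum() - (d * v1**2).sum() / n) / (n - 1)
        # degenerate kernels (no between-line variance) get a neutral scale
        c_k[nm] = float(c) if c > 1e-8 else 1.0
    # scaled-inv-chi2(nu, tau2): prior mean nu*tau2/(nu-2) matched to the
    # requested fraction of phenotypic variance, divided by the kernel scale
    tau2 = {nm: frac * vy * (nu - 2.0) / nu / c_k[nm] for nm in names}
    tau2_e = 0.5 * vy * (nu - 2.0) / nu

    ystar = y.copy()
    mu = float(np.mean(y[obs]))
    ystar[~obs] = mu
    sig2 = {nm: frac * vy / c_k[nm] for nm in names}
    sig2_e = 0.5 * vy
    if fixed:
        for nm in names:
            if nm in fixed:
                sig2[nm] = float(fixed[nm])
        if "resid" in fixed:
            sig2_e = float(fixed["resid"])
    a = {nm: np.zeros(len(eig[nm][0])) for nm in names}
    u = {nm: np.zeros(n) for nm in names}

    keep = 0
    acc_mu = acc_mu2 = 0.0
    acc_s = {nm: 0.0 for nm in names}
    acc_s2 = {nm: 0.0 for nm in names}
    acc_e = acc_e2 = 0.0
    acc_u = {nm: np.zeros(n) for nm in names}
    acc_g = np.zeros(n)
    acc_y = np.zeros(n)
    trace_rows = [] if keep_trace else None

    n_obs = int(obs.sum())
    for it in range(cfg.n_iter):
        total_u = sum(u.values()) if nk else np.zeros(n)
        # mu | rest
        resid = ystar - total_u
        mu = rng.normal(resid.mean(), np.sqrt(sig2_e / n))
        # u_k | rest, in the eigenbasis of K_k
        for nm in names:
            d, V = eig[nm]
            r = ystar - mu - (total_u - u[nm])
            rt = V.T @ r
            prec = 1.0 / sig2_e + 1.0 / (sig2[nm] * d)
            mean = rt / sig2_e / prec
            a[nm] = mean + rng.standard_normal(len(d)) / np.sqrt(prec)
            new_u = V @ a[nm]
            total_u += new_u - u[nm]
            u[nm] = new_u
        # variance components
        if not fixed or not all(nm in fixed for nm in names):
            for nm in names:
                if fixed and nm in fixed:
                    continue
                d, _ = eig[nm]
                ss = float(np.sum(a[nm] ** 2 / d)) + nu * tau2[nm]
                df = nu + len(d)
                sig2[nm] = ss / rng.chisquare(df)
        e = ystar - mu - total_u
        if not (fixed and "resid" in fixed):
            ss = float(e @ e) + nu * tau2_e
            sig2_e = ss / rng.chisquare(nu + n)
        if sig2_e > 1e6 * vy or any(s > 1e6 * vy for s in sig2.values()):
            raise RuntimeError(
                f"divergent chain at iter {it}: sig2_e={sig2_e:.3g}, sig2={sig2}")
        # missing phenotypes (test lines) as latent data
        miss = ~obs
        if miss.any():
            ystar[miss] = mu + total_u[miss] + \
                rng.standard_normal(miss.sum()) * np.sqrt(sig2_e)
        # accumulate
        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            keep += 1
            acc_mu += mu
            acc_mu2 += mu * mu
            for nm in names:
                acc_s[nm] += sig2[nm]
                acc_s2[nm] += sig2[nm] ** 2
                acc_u[nm] += u[nm]
            acc_e += sig2_e
            acc_e2 += sig2_e ** 2
            acc_g += mu + total_u
            acc_y += ystar
            if trace_rows is not None:
                trace_rows.append(
                    {"mu": mu, "var_resid": sig2_e,
                     **{f"var_{nm}": sig2[nm] for nm in names}})

    def _sd(s, s2):
        v = s2 / keep - (s / keep) ** 2
        return float(np.sqrt(max(v, 0.0)))

    return PosteriorSummary(
        label=label,
        mu=acc_mu / keep, mu_sd=_sd(acc_mu, acc_mu2),
        var_kernel={nm: acc_s[nm] / keep for nm in names},
        var_kernel_sd={nm: _sd(acc_s[nm], acc_s2[nm]) for nm in names},
        var_resid=acc_e / keep, var_resid_sd=_sd(acc_e, acc_e2),
        u={nm: acc_u[nm] / keep for nm in names},
        genetic_values=acc_g / keep,
        yhat=acc_y / keep,
        n_samples=keep,
        kernel_scale=c_k,
        trace=None if trace_rows is None else __import__("pandas").DataFrame(trace_rows),
    )


# ---------------------------------------------------------------------------
# thin functional wrappers
# ---------------------------------------------------------------------------

def fit(y, spec: ModelSpec, mcmc: MCMCConfig | None = None,
        fixed_variances: dict | None = None) -> PosteriorSummary:
    """Fit the multi-kernel model; NaN entries of ``y`` are predicted."""
    mcmc = mcmc or MCMCConfig()
    est = KernelBayesRegressor(
        n_iter=mcmc.n_iter, burn_in=mcmc.burn_in, thin=mcmc.thin,
        seed=mcmc.seed, prior_df=mcmc.prior_df,
        prior_scale_fraction=mcmc.prior_scale_fraction,
        fixed_variances=fixed_variances, label=spec.label,
    )
    est.fit(spec, y)
    return est.summary_


def predict(summary: PosteriorSummary, test_lines) -> np.ndarray:
    return summary.predict(test_lines)


def rkhs_ka(y, kernel_set: KernelSet, mcmc: MCMCConfig | None = None,
            label: str = "RKHS") -> PosteriorSummary:
    """RKHS kernel averaging: one variance per Gaussian bandwidth kernel."""
    return fit(y, ModelSpec(kernel_set, label), mcmc)


def gblup_closed_form(K: np.ndarray, y: np.ndarray, sigma2_g: float,
                      sigma2_e: float) -> np.ndarray:
    """Fixed-variance GBLUP via the conditional multivariate-normal mean:
    u_hat = K[:, obs] (K[obs, obs] + lambda I)^-1 (y_obs - mean).  Serves as
    the mixed-model-equations oracle for the sampler."""
    y = np.asarray(y, float)
    obs = ~np.isnan(y)
    lam = sigma2_e / sigma2_g
    Koo = K[np.ix_(obs, obs)] + lam * np.eye(int(obs.sum()))
    alpha = np.linalg.solve(Koo, y[obs] - y[obs].mean())
    return y[obs].mean() + K[:, obs] @ alpha
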