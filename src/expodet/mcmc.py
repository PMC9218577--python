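"""Gibbs sampler for Bayesian linear regression of log-concentrations with
left-censored observations.

Model (log scale):

    y_i = x_i' beta + b_{j(i)} + eps_i,   eps_i ~ N(0, sigma_w^2)
    b_j ~ N(0, sigma_b^2)                 (random-intercept variant only)

A measurement below its limit of detection is treated as left-censored at
ln(LOD) and imputed at every iteration from the normal conditional truncated
above at that bound (data augmentation), so censored rows contribute exactly
their censored likelihood.

Priors: coefficients N(0, 1e6); in the fixed-effect variant the residual
variance gets an inverse-gamma(0.1, 0.1) prior; in the random-intercept
variant both standard deviations get uniform priors on [ln 1.01, ln 500],
updated by slice sampling on the SD scale.

Chain schedule: ``burn_in`` raw iterations are discarded, then
``thin * kept_iterations`` raw iterations are run keeping every ``thin``-th
draw (thin-then-keep), so the returned chain always has ``kept_iterations``
rows.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg, special

from .datamodel import DesignMatrix

__all__ = [
    "PriorSpec",
    "McmcSettings",
    "PosteriorChain",
    "CensoredBayesLM",
    "CensoredBayesResults",
    "fit_censored_fixed",
    "fit_censored_random_intercept",
    "sample_truncated_normal_upper",
    "slice_sample_bounded",
    "mcse",
    "credible_interval",
    "derive_seed",
]

SD_LOWER = math.log(1.01)
SD_UPPER = math.log(500.0)

#: More than this many subjects must have repeated measurements before the
#: random-intercept variant is allowed.
REPEATED_MEASURES_MIN_SUBJECTS = 5


@dataclass(frozen=True)
class PriorSpec:
    """Weakly informative priors for the censored regression."""

    coef_mean: float = 0.0
    coef_variance: float = 1.0e6
    ig_shape: float = 0.1
    ig_scale: float = 0.1
    sd_lower: float = SD_LOWER
    sd_upper: float = SD_UPPER

    def __post_init__(self):
        if not (self.coef_variance > 0 and self.ig_shape > 0 and self.ig_scale > 0):
            raise ValueError("prior variance and inverse-gamma parameters must be positive")
        if not (0 < self.sd_lower < self.sd_upper):
            raise ValueError("SD prior bounds must be positive and ordered")


@dataclass(frozen=True)
class McmcSettings:
    """Chain schedule. Defaults are the full-scale production schedule:
    5,000 burn-in iterations; 10,000 kept draws thinned by 60 for covariate
    models (use ``kept_iterations=20000, thin=1`` for descriptive
    intercept-only models)."""

    burn_in: int = 5000
    kept_iterations: int = 10000
    thin: int = 60
    seed: int = 0
    n_chains: int = 1

    def __post_init__(self):
        if min(self.burn_in, self.kept_iterations, self.thin, self.n_chains) < 1:
            raise ValueError("all MCMC settings must be positive")

    def with_seed(self, seed: int) -> "McmcSettings":
        return replace(self, seed=int(seed))


def derive_seed(root_seed: int, *keys) -> int:
    """Deterministically split a root seed, e.g. per model id.

    Uses numpy's SeedSequence over ``(root_seed, *keys)``; the result is a
    plain int below 2**31 so it can be stored in manifests.
    """
    ss = np.random.SeedSequence([int(root_seed) & 0x7FFFFFFF] + [int(k) & 0x7FFFFFFF for k in keys])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass
class PosteriorChain:
    """Kept, thinned draws of one fitted model."""

    draws: np.ndarray  # kept x n_params
    parameter_names: list
    settings: McmcSettings
    model_id: object = None

    def __post_init__(self):
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 2 or self.draws.shape[1] != len(self.parameter_names):
            raise ValueError("draws must be kept x len(parameter_names)")

    def param(self, name: str) -> np.ndarray:
        return self.draws[:, self.parameter_names.index(name)]

    def has(self, name: str) -> bool:
        return name in self.parameter_names

    def sigma_total(self) -> np.ndarray:
        """Per-draw total residual SD: sqrt(sigma_w^2 + sigma_b^2)."""
        s = self.param("sigma_within") ** 2
        if self.has("sigma_between"):
            s = s + self.param("sigma_between") ** 2
        return np.sqrt(s)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.draws, columns=self.parameter_names)
        df.insert(0, "iteration", np.arange(1, len(df) + 1))
        return df

    def export(self, csv_path, json_path=None) -> None:
        import json

        self.to_frame().to_csv(csv_path, index=False)
        if json_path is not None:
            meta = {
                "model_id": self.model_id,
                "settings": {
                    "burn_in": self.settings.burn_in,
                    "kept_iterations": self.settings.kept_iterations,
                    "thin": self.settings.thin,
                    "seed": self.settings.seed,
                },
                "mcse": {n: mcse(self.param(n)) for n in self.parameter_names},
            }
            with open(json_path, "w", encoding="utf-8") as fh:
                json.dump(meta, fh, indent=1)


# ---------------------------------------------------------------------------
# Primitive samplers


def _tail_lower_truncated(a: np.ndarray, rng) -> np.ndarray:
    """Standard normal truncated below at a >= 0, by exponential rejection
    (Robert 1995). Vectorised; loops only over rejected entries."""
    a = np.asarray(a, dtype=float)
    out = np.empty_like(a)
    pending = np.ones(a.shape, dtype=bool)
    lam = 0.5 * (a + np.sqrt(a * a + 4.0))
    while pending.any():
        idx = np.flatnonzero(pending)
        x = a[idx] - np.log(rng.random(idx.size)) / lam[idx]
        accept = np.log(rng.random(idx.size)) <= -0.5 * (x - lam[idx]) ** 2
        took = idx[accept]
        out[took] = x[accept]
        pending[took] = False
    return out


def sample_truncated_normal_upper(mean, sd, upper, rng):
    """Draw from Normal(mean, sd^2) conditioned on value <= upper.

    Stable far into the lower tail: the bulk uses the inverse CDF, entries
    with standardized bound below -6 use an exponential rejection sampler.
    Broadcasts over array arguments; returns a scalar for scalar input.
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    upper = np.asarray(upper, dtype=float)
    if np.any(sd <= 0):
        raise ValueError("sd must be positive")
    scalar = mean.ndim == 0 and sd.ndim == 0 and upper.ndim == 0
    mean, sd, upper = np.broadcast_arrays(mean, sd, upper)
    z = (upper - mean) / sd
    out = np.empty(z.shape, dtype=float)

    bulk = z > -6.0
    if bulk.any():
        u = rng.random(int(bulk.sum()))
        # u * Phi(z), inverted; Phi(z) >= Phi(-6) ~ 1e-9 keeps ndtri accurate
        out[bulk] = special.ndtri(u * special.ndtr(z[bulk]))
    tail = ~bulk
    if tail.any():
        out[tail] = -_tail_lower_truncated(-z[tail], rng)
    draw = mean + sd * out
    return float(draw) if scalar else draw


def slice_sample_bounded(log_density, x0: float, lower: float, upper: float, rng) -> float:
    """One slice-sampling update of a scalar on a bounded interval.

    The bounds form the initial bracket (no step-out needed); the bracket
    shrinks toward the current point until a draw lands inside the slice.
    """
    if not (lower <= x0 <= upper):
        x0 = min(max(x0, lower), upper)
    logy = log_density(x0) + math.log(rng.random())
    lo, hi = lower, upper
    for _ in range(200):
        x1 = rng.uniform(lo, hi)
        if log_density(x1) >= logy:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0  # pathological shrinkage; keep current point


# ---------------------------------------------------------------------------
# Chain diagnostics


def mcse(draws) -> float:
    """Batch-means Monte Carlo standard error of the chain mean."""
    x = np.asarray(draws, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 draws")
    b = max(int(math.floor(math.sqrt(n))), 2)
    m = n // b
    means = x[: m * b].reshape(m, b).mean(axis=1)
    if m < 2:
        return 0.0
    var_bm = b * means.var(ddof=1)
    return float(math.sqrt(var_bm / n))


def credible_interval(draws, level: float):
    """Equal-tailed posterior interval from chain quantiles (linear
    interpolation rule of numpy.quantile)."""
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(np.asarray(draws, dtype=float), [a, 1.0 - a])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# The model


class CensoredBayesLM:
    """Bayesian linear model for left-censored log-concentrations.

    Parameters
    ----------
    design : DesignMatrix
        Response with censoring bounds, predictors, and subject indices.
    priors : PriorSpec
    random_intercept : bool
        Include a per-subject random intercept. Requires more than
        ``REPEATED_MEASURES_MIN_SUBJECTS`` subjects with repeated
        measurements in the design.
    """

    def __init__(self, design: DesignMatrix, priors: PriorSpec | None = None,
                 random_intercept: bool = False):
        self.design = design
        self.priors = priors or PriorSpec()
        self.random_intercept = bool(random_intercept)

        if design.n < 1:
            raise ValueError("empty design")
        if design.censored.all():
            raise ValueError(
                "every row is censored; no regression is estimable — "
                "use a descriptive (distribution-only) treatment instead"
            )
        if self.random_intercept and design.n_repeat_subjects() <= REPEATED_MEASURES_MIN_SUBJECTS:
            raise ValueError(
                f"random-intercept model needs more than {REPEATED_MEASURES_MIN_SUBJECTS} "
                f"subjects with repeated measurements (found {design.n_repeat_subjects()}); "
                "use the fixed-effect variant"
            )
        if np.linalg.matrix_rank(design.X) < design.p:
            warnings.warn(
                "design matrix is rank deficient; coefficients are not separately "
                "identifiable (the wide prior keeps the posterior proper) — check "
                "MCSE and traces",
                UserWarning,
                stacklevel=2,
            )

    # -- conditional updates -------------------------------------------------

    def fit(self, settings: McmcSettings | None = None, model_id=None) -> "CensoredBayesResults":
        settings = settings or McmcSettings()
        d = self.design
        pr = self.priors
        rng = np.random.default_rng(settings.seed)

        X = d.X
        n, p = X.shape
        cens = d.censored
        bound = d.bound
        J = len(d.subject_labels)
        subj = d.subject_index

        # initialisation: censored rows at their bound, ridge least squares
        y = d.response.copy()
        XtX = X.T @ X
        beta = linalg.solve(XtX + 1e-8 * np.eye(p), X.T @ y, assume_a="pos")
        resid = y - X @ beta
        s0 = float(resid.std(ddof=min(p, n - 1))) if n > p else 1.0
        sigma_w = min(max(s0 if s0 > 0 else 0.5, pr.sd_lower), pr.sd_upper)
        sigma_b = min(max(0.5 * sigma_w, pr.sd_lower), pr.sd_upper)
        b = np.zeros(J)

        prior_prec = np.eye(p) / pr.coef_variance
        prior_mean_term = (pr.coef_mean / pr.coef_variance) * np.ones(p)

        total = settings.burn_in + settings.thin * settings.kept_iterations
        names = list(d.columns) + ["sigma_within"]
        if self.random_intercept:
            names.append("sigma_between")
        kept = np.empty((settings.kept_iterations, len(names)))
        k = 0

        n_j = np.bincount(subj, minlength=J).astype(float)
        any_cens = bool(cens.any())

        for it in range(total):
            mu_row = X @ beta + (b[subj] if self.random_intercept else 0.0)

            # (a) impute latent responses for censored rows
            if any_cens:
                y[cens] = sample_truncated_normal_upper(
                    mu_row[cens], sigma_w, bound[cens], rng
                )

            # (b) coefficient block from its conjugate normal conditional
            resp = y - (b[subj] if self.random_intercept else 0.0)
            prec = XtX / sigma_w**2 + prior_prec
            chol = linalg.cholesky(prec, lower=True)
            m = linalg.cho_solve((chol, True), X.T @ resp / sigma_w**2 + prior_mean_term)
            beta = m + linalg.solve_triangular(chol.T, rng.standard_normal(p), lower=False)

            if self.random_intercept:
                # (d) subject intercept conditionals
                r = y - X @ beta
                sums = np.bincount(subj, weights=r, minlength=J)
                var_j = 1.0 / (n_j / sigma_w**2 + 1.0 / sigma_b**2)
                mean_j = var_j * sums / sigma_w**2
                b = mean_j + np.sqrt(var_j) * rng.standard_normal(J)

                # (e) SD updates under the bounded uniform prior, on SD scale
                ssr = float(np.sum((r - b[subj]) ** 2))
                sigma_w = slice_sample_bounded(
                    lambda s: -n * math.log(s) - ssr / (2.0 * s * s),
                    sigma_w, pr.sd_lower, pr.sd_upper, rng,
                )
                ssb = float(np.sum(b**2))
                sigma_b = slice_sample_bounded(
                    lambda s: -J * math.log(s) - ssb / (2.0 * s * s),
                    sigma_b, pr.sd_lower, pr.sd_upper, rng,
                )
            else:
                # (c) residual variance from its inverse-gamma conditional
                ssr = float(np.sum((y - X @ beta) ** 2))
                shape = pr.ig_shape + 0.5 * n
                scale = pr.ig_scale + 0.5 * ssr
                sigma_w = math.sqrt(scale / rng.gamma(shape))

            t = it - settings.burn_in
            if t >= 0 and (t + 1) % settings.thin == 0:
                row = list(beta) + [sigma_w]
                if self.random_intercept:
                    row.append(sigma_b)
                kept[k] = row
                k += 1

        chain = PosteriorChain(
            draws=kept, parameter_names=names, settings=settings, model_id=model_id
        )
        return CensoredBayesResults(model=self, chain=chain)


@dataclass
class CensoredBayesResults:
    """Posterior summaries of a fitted :class:`CensoredBayesLM`."""

    model: CensoredBayesLM
    chain: PosteriorChain

    @property
    def parameter_names(self):
        return self.chain.parameter_names

    @property
    def params(self) -> pd.Series:
        """Posterior medians."""
        return pd.Series(
            np.median(self.chain.draws, axis=0), index=self.parameter_names, name="median"
        )

    def ci(self, level: float = 0.95) -> pd.DataFrame:
        rows = [credible_interval(self.chain.param(n), level) for n in self.parameter_names]
        return pd.DataFrame(rows, index=self.parameter_names, columns=["lower", "upper"])

    @property
    def mcse_(self) -> pd.Series:
        return pd.Series(
            [mcse(self.chain.param(n)) for n in self.parameter_names],
            index=self.parameter_names,
            name="mcse",
        )

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        tab = self.ci(level)
        tab.insert(0, "median", self.params)
        tab["mcse"] = self.mcse_
        tab.columns = ["median", f"ci{int(level*100)}_low", f"ci{int(level*100)}_high", "mcse"]
        return tab

    def __str__(self):  # pragma: no cover - cosmetic
        kind = "random-intercept" if self.model.random_intercept else "fixed-effect"
        head = (
            f"Censored Bayesian linear model ({kind}), n={self.model.design.n}, "
            f"censored={int(self.model.design.censored.sum())}\n"
        )
        return head + self.summary().round(4).to_string()


def fit_censored_fixed(design: DesignMatrix, priors: PriorSpec | None = None,
                       settings: McmcSettings | None = None, model_id=None) -> PosteriorChain:
    """Fixed-effect censored regression; returns the posterior chain."""
    return CensoredBayesLM(design, priors, random_intercept=False).fit(settings, model_id).chain


def fit_censored_random_intercept(design: DesignMatrix, priors: PriorSpec | None = None,
                                  settings: McmcSettings | None = None,
                                  model_id=None) -> PosteriorChain:
    """Subject random-intercept censored regression; returns the chain."""
    return CensoredBayesLM(design, priors, random_intercept=True).fit(settings, model_id).chain
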