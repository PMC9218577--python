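"""Bayesian model averaging over all admissible determinant subsets.

Every subset of the screened (notable) determinants that contains no
collinear or nested pair is fitted as a censored Bayesian regression (the
null, intercept-only model included, for the GSD-reduction metric). For each
determinant the averaged posterior is formed *across only the models that
contain it* — restricted averaging, which deliberately avoids shrinkage
toward zero for determinants excluded from many models by collinearity.
Unweighted averaging (the default) pools member-model draws into an
equal-weight mixture posterior; see :func:`average_coefficient` for the
iteration-wise mean variant used when explicit model weights (e.g.
proportional to GSD reduction) are supplied.

Effect sizes are reported as percent change
``(exp(beta * units) - 1) * 100`` relative to the reference condition, with
``units`` the determinant's declared unit scale (1 for categorical).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import StudyDataset, build_design_matrix
from .mcmc import (
    CensoredBayesLM,
    McmcSettings,
    PosteriorChain,
    PriorSpec,
    credible_interval,
    derive_seed,
)
from .screening import ExclusionSet, choose_model_kind

logger = logging.getLogger(__name__)

MAX_CANDIDATE_SUBSETS = 2**24


@dataclass(frozen=True)
class ModelSpec:
    model_id: int
    determinants: frozenset
    includes_null: bool = False


@dataclass
class ModelSpace:
    """Admissible subsets of the notable determinants."""

    models: list
    determinant_order: list
    membership_counts: dict
    total_models: int  # non-null admissible models

    def containing(self, determinant: str) -> list:
        return [m for m in self.models if determinant in m.determinants]

    @property
    def null_model(self) -> ModelSpec:
        for m in self.models:
            if m.includes_null:
                return m
        raise LookupError("no null model in space")

    def to_json_dict(self) -> dict:
        return {
            "determinants": list(self.determinant_order),
            "total_models": self.total_models,
            "membership_counts": dict(self.membership_counts),
            "models": [
                {"model_id": m.model_id, "determinants": sorted(m.determinants)}
                for m in self.models
            ],
        }


@dataclass
class AveragedCoefficient:
    """Model-averaged posterior for one coefficient of one determinant."""

    determinant: str
    coefficient: str
    n_models: int
    pct_models: float
    beta_median: float
    beta_ci95: tuple
    pct_change_median: float
    pct_change_ci95: tuple
    units_applied: float = 1.0

    @property
    def notable_95(self) -> bool:
        lo, hi = self.beta_ci95
        return bool(lo > 0 or hi < 0)


@dataclass
class BMAResult:
    """Full averaging output for one task group and analyte."""

    task_group: object
    analyte: str
    coefficients: list
    intercept_reference_gm_ppb: float
    gsd_null: float
    gsd_by_model: dict
    space: ModelSpace

    def to_table(self) -> pd.DataFrame:
        rows = []
        for c in self.coefficients:
            rows.append(
                {
                    "determinant": c.determinant,
                    "coefficient": c.coefficient,
                    "n_models": c.n_models,
                    "pct_models": c.pct_models,
                    "beta_median": c.beta_median,
                    "beta_ci95_low": c.beta_ci95[0],
                    "beta_ci95_high": c.beta_ci95[1],
                    "pct_change_median": c.pct_change_median,
                    "pct_change_ci95_low": c.pct_change_ci95[0],
                    "pct_change_ci95_high": c.pct_change_ci95[1],
                    "notable_95": c.notable_95,
                    "units_applied": c.units_applied,
                }
            )
        return pd.DataFrame(rows)


def enumerate_models(notable, exclusions: ExclusionSet | None = None) -> ModelSpace:
    """All subsets of the notable determinants with no excluded pair.

    Deterministic order: subsets are visited by binary counting over the
    determinant indices (lexicographic by index), the empty set first and
    flagged as the null model. Membership counts run over non-null models.
    """
    notable = list(notable)
    if not notable:
        raise ValueError("no notable determinants to enumerate")
    if 2 ** len(notable) > MAX_CANDIDATE_SUBSETS:
        raise ValueError(
            f"{len(notable)} determinants give >2^24 candidate subsets; "
            "reduce the determinant count before enumerating"
        )
    exclusions = exclusions or ExclusionSet()
    banned = exclusions.all_pairs
    models = []
    counts = {name: 0 for name in notable}
    model_id = 0
    for mask in range(2 ** len(notable)):
        subset = frozenset(
            notable[i] for i in range(len(notable)) if mask & (1 << i)
        )
        if any(
            frozenset((a, b)) in banned for a, b in itertools.combinations(sorted(subset), 2)
        ):
            continue
        models.append(ModelSpec(model_id=model_id, determinants=subset,
                                includes_null=(len(subset) == 0)))
        if subset:
            for name in subset:
                counts[name] += 1
        model_id += 1
    total = sum(1 for m in models if not m.includes_null)
    return ModelSpace(
        models=models, determinant_order=notable, membership_counts=counts, total_models=total
    )


def _chain_cache_key(design, determinants, settings: McmcSettings, seed: int,
                     random_intercept: bool) -> str:
    import hashlib

    h = hashlib.sha1()
    h.update(design.response.tobytes())
    h.update(design.bound.tobytes())
    h.update(design.censored.tobytes())
    h.update(design.X.tobytes())
    h.update(design.subject_index.tobytes())
    h.update(repr(sorted(determinants)).encode())
    h.update(
        f"{settings.burn_in}:{settings.kept_iterations}:{settings.thin}:"
        f"{seed}:{random_intercept}".encode()
    )
    return h.hexdigest()


def fit_model_space(
    dataset: StudyDataset,
    space: ModelSpace,
    task_filter="overall",
    settings: McmcSettings | None = None,
    priors: PriorSpec | None = None,
    random_intercept: bool | None = None,
    cache_dir=None,
) -> tuple:
    """Fit every model in the space; returns ``(chains, manifest)``.

    One chain per model with a per-model seed derived from the run seed and
    the model id. When ``cache_dir`` is given, chains are cached on disk
    keyed by (data, model determinants, settings, seed) so regeneration never
    silently refits. A failed member model is dropped from averaging with a
    loud warning and recorded in the manifest.
    """
    settings = settings or McmcSettings()
    probe = build_design_matrix(dataset, [], task_filter)
    if random_intercept is None:
        random_intercept = choose_model_kind(probe, task_filter) == "random_intercept"

    chains: dict = {}
    manifest = {
        "task_filter": str(task_filter),
        "analyte": dataset.analyte,
        "random_intercept": bool(random_intercept),
        "settings": {
            "burn_in": settings.burn_in,
            "kept_iterations": settings.kept_iterations,
            "thin": settings.thin,
            "root_seed": settings.seed,
        },
        "models": [],
        "failures": [],
    }
    for m in space.models:
        seed = derive_seed(settings.seed, m.model_id)
        try:
            design = build_design_matrix(dataset, sorted(m.determinants), task_filter)
            cache_path = None
            if cache_dir is not None:
                from pathlib import Path

                key = _chain_cache_key(design, m.determinants, settings, seed, random_intercept)
                cache_path = Path(cache_dir) / f"chain_{key}.npz"
            if cache_path is not None and cache_path.exists():
                with np.load(cache_path, allow_pickle=False) as payload:
                    chains[m.model_id] = PosteriorChain(
                        draws=payload["draws"],
                        parameter_names=[str(n) for n in payload["names"]],
                        settings=settings.with_seed(seed),
                        model_id=m.model_id,
                    )
            else:
                lm = CensoredBayesLM(design, priors, random_intercept=random_intercept)
                chains[m.model_id] = lm.fit(settings.with_seed(seed), model_id=m.model_id).chain
                if cache_path is not None:
                    cache_path.parent.mkdir(parents=True, exist_ok=True)
                    np.savez_compressed(
                        cache_path,
                        draws=chains[m.model_id].draws,
                        names=np.array(chains[m.model_id].parameter_names),
                    )
            manifest["models"].append(
                {"model_id": m.model_id, "determinants": sorted(m.determinants), "seed": seed}
            )
        except Exception as exc:  # pragma: no cover - defensive path
            warnings.warn(
                f"model {m.model_id} ({sorted(m.determinants)}) failed and is dropped "
                f"from averaging: {exc}",
                UserWarning,
                stacklevel=2,
            )
            manifest["failures"].append({"model_id": m.model_id, "error": str(exc)})
    return chains, manifest


def _block_columns(chains, space, determinant) -> list:
    for m in space.containing(determinant):
        chain = chains.get(m.model_id)
        if chain is not None:
            return [n for n in chain.parameter_names if n.split("[", 1)[0] == determinant]
    raise ValueError(f"determinant {determinant!r} appears in no fitted model")


def average_coefficient(chains: dict, space: ModelSpace, determinant: str, weights=None,
                        method: str = "mixture") -> dict:
    """Model-averaged draws per coefficient of one determinant, restricted to
    the models containing it (avoiding shrinkage toward zero from models that
    omit it).

    ``method="mixture"`` (default, equal model weights) pools the kept draws
    of the member models — the averaged posterior is the equal-weight mixture
    of member posteriors, which preserves each member's posterior spread and
    keeps 95% intervals calibrated. ``method="iteration_mean"`` instead takes
    the (weighted) mean of the coefficient's draw at each kept iteration t
    across member models; because member chains are independent, this
    narrows the averaged distribution when models agree, and is kept for the
    weighted-averaging variant (``weights`` maps model_id -> weight,
    normalised internally; equal weights reproduce the unweighted mean).

    Returns ``{coefficient_label: averaged draws}``.
    """
    members = [m for m in space.containing(determinant) if m.model_id in chains]
    if not members:
        raise ValueError(f"determinant {determinant!r} appears in no fitted model")
    labels = _block_columns(chains, space, determinant)
    if weights is not None and method == "mixture":
        method = "iteration_mean"  # weighting is defined iteration-wise
    out = {}
    if method == "mixture":
        for label in labels:
            out[label] = np.concatenate(
                [chains[m.model_id].param(label) for m in members]
            )
        return out
    if method != "iteration_mean":
        raise ValueError(f"unknown averaging method {method!r}")
    if weights is None:
        w = np.ones(len(members))
    else:
        w = np.array([float(weights[m.model_id]) for m in members])
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("weights must be nonnegative with positive sum")
    w = w / w.sum()
    for label in labels:
        stacked = np.stack([chains[m.model_id].param(label) for m in members], axis=1)
        out[label] = stacked @ w
    return out


def percent_change(beta_draws, unit_scale: float = 1.0):
    """Percent change per ``unit_scale`` raw units: (exp(b*u) - 1) * 100.

    Returns ``(draws, median, (ci_low, ci_high))``. The summary median and CI
    are the exact monotone transforms of the beta-draw median and quantiles,
    so notability on the beta and percent-change scales always agrees.
    """
    if not (unit_scale > 0):
        raise ValueError("unit_scale must be positive")
    beta = np.asarray(beta_draws, dtype=float)

    def transform(b):
        return (np.exp(b * unit_scale) - 1.0) * 100.0

    lo, hi = credible_interval(beta, 0.95)
    return (
        transform(beta),
        float(transform(np.median(beta))),
        (float(transform(lo)), float(transform(hi))),
    )


def gsd_reduction(null_chain: PosteriorChain, model_chain: PosteriorChain) -> float:
    """Null-model overall GSD minus covariate-model overall GSD (posterior
    medians of exp(total residual SD)); the variance-explained surrogate."""
    gsd_null = float(np.median(np.exp(null_chain.sigma_total())))
    gsd_model = float(np.median(np.exp(model_chain.sigma_total())))
    return gsd_null - gsd_model


def flag_notable(coefficients) -> list:
    """Re-assert the 95% notable rule on averaged coefficients (an interval
    endpoint exactly at 0 counts as containing 0 — not notable)."""
    for c in coefficients:
        lo, hi = c.beta_ci95
        assert c.notable_95 == bool(lo > 0 or hi < 0)
    return list(coefficients)


class BayesianModelAveraging:
    """Model-averaging analysis for one task group and analyte.

    Parameters
    ----------
    dataset : StudyDataset
    notable : sequence of determinant names that passed screening
    exclusions : ExclusionSet
    task_filter : task group name or explicit label set
    weights : None | "gsd_reduction" | mapping model_id -> weight
    """

    def __init__(self, dataset, notable, exclusions=None, task_filter="overall",
                 priors: PriorSpec | None = None, weights=None,
                 random_intercept: bool | None = None):
        self.dataset = dataset
        self.notable = list(notable)
        self.exclusions = exclusions or ExclusionSet()
        self.task_filter = task_filter
        self.priors = priors
        self.weights = weights
        self.random_intercept = random_intercept
        self.space = enumerate_models(self.notable, self.exclusions)

    def fit(self, settings: McmcSettings | None = None, cache_dir=None) -> "BMAResults":
        settings = settings or McmcSettings()
        chains, manifest = fit_model_space(
            self.dataset,
            self.space,
            self.task_filter,
            settings,
            self.priors,
            self.random_intercept,
            cache_dir=cache_dir,
        )
        null_id = self.space.null_model.model_id
        null_chain = chains[null_id]
        gsd_by_model = {
            m.model_id: gsd_reduction(null_chain, chains[m.model_id])
            for m in self.space.models
            if m.model_id in chains
        }

        weights = self.weights
        if weights == "gsd_reduction":
            weights = {mid: max(red, 0.0) + 1e-12 for mid, red in gsd_by_model.items()}
        elif weights is not None and not hasattr(weights, "__getitem__"):
            raise ValueError("weights must be None, 'gsd_reduction', or a mapping")

        coefficients = []
        for name in self.notable:
            members = [m for m in self.space.containing(name) if m.model_id in chains]
            if not members:
                logger.warning("determinant %r dropped: no fitted member models", name)
                continue
            spec = self.dataset.spec(name)
            unit = spec.unit_scale if spec.kind == "continuous" else 1.0
            averaged = average_coefficient(chains, self.space, name, weights=(
                None if weights is None else weights
            ))
            n_models = self.space.membership_counts[name]
            pct = 100.0 * n_models / self.space.total_models if self.space.total_models else 0.0
            for label, draws in averaged.items():
                _, pc_med, pc_ci = percent_change(draws, unit)
                coefficients.append(
                    AveragedCoefficient(
                        determinant=name,
                        coefficient=label,
                        n_models=n_models,
                        pct_models=pct,
                        beta_median=float(np.median(draws)),
                        beta_ci95=credible_interval(draws, 0.95),
                        pct_change_median=pc_med,
                        pct_change_ci95=pc_ci,
                        units_applied=unit,
                    )
                )
        flag_notable(coefficients)

        # reference GM: intercept draws averaged iteration-wise over all models
        inter = np.stack([c.param("intercept") for c in chains.values()], axis=1).mean(axis=1)
        result = BMAResult(
            task_group=self.task_filter,
            analyte=self.dataset.analyte,
            coefficients=coefficients,
            intercept_reference_gm_ppb=float(np.exp(np.median(inter))),
            gsd_null=float(np.median(np.exp(null_chain.sigma_total()))),
            gsd_by_model=gsd_by_model,
            space=self.space,
        )
        return BMAResults(model=self, result=result, chains=chains, manifest=manifest)


@dataclass
class BMAResults:
    """Fitted model-averaging run: averaged table plus raw member chains."""

    model: BayesianModelAveraging
    result: BMAResult
    chains: dict
    manifest: dict

    def summary(self) -> pd.DataFrame:
        return self.result.to_table()

    @property
    def intercept_reference_gm_ppb(self) -> float:
        return self.result.intercept_reference_gm_ppb
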