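"""Bayesian descriptive exposure summaries.

Each task (or instantaneous activity/source label) gets an intercept-only
censored lognormal fit; the posterior of (mu, sigma) is transformed per draw
into the geometric mean GM = exp(mu), geometric standard deviation
GSD = exp(sigma) and 95th percentile P95 = exp(mu + 1.645 sigma). Under the
repeated-measures model sigma is the *total* spread
sqrt(sigma_within^2 + sigma_between^2), so one GSD summarises between- plus
within-worker variability (both components are also exported).

Also here: short-term exposure limit (STEL) exceedance tabulation over the
15-minute samples and the between-analyte rank correlation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .datamodel import DesignMatrix, StudyDataset
from .mcmc import (
    REPEATED_MEASURES_MIN_SUBJECTS,
    CensoredBayesLM,
    McmcSettings,
    PosteriorChain,
    PriorSpec,
    credible_interval,
)

logger = logging.getLogger(__name__)

Z_P95 = 1.645  # standard-normal 95th percentile used for lognormal P95

#: NIOSH short-term exposure limits, ppb.
STEL_PPB = {"diacetyl": 25.0, "pentanedione_23": 31.0}

#: Default descriptive chain schedule: 20,000 kept draws, no thinning
#: (intercept-only chains mix essentially independently).
DESCRIPTIVE_SETTINGS = McmcSettings(burn_in=5000, kept_iterations=20000, thin=1)


@dataclass
class LognormalSummary:
    """Posterior GM / GSD / P95 (medians with 95% CIs) for one group."""

    group: str
    n: int
    k: int
    pct_bdl: float
    gm_ppb: float
    gm_ci: tuple
    gsd: float
    gsd_ci: tuple
    p95_ppb: float
    p95_ci: tuple
    estimable: bool = True
    model_kind: str = "random_intercept"


@dataclass
class ExceedanceSummary:
    """Count of comparison-duration samples above a short-term limit."""

    task: str
    limit_ppb: float
    n_eligible: int
    n_exceed: int

    @property
    def pct_exceed(self) -> float | None:
        if self.n_eligible == 0:
            return None
        return round_half_away(100.0 * self.n_exceed / self.n_eligible, 0)


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (so 0.5 -> 1, -0.5 -> -1)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def _intercept_design(records) -> DesignMatrix:
    response = np.array([r.log_bound for r in records])
    bound = np.log([r.lod_ppb for r in records])
    censored = np.array([r.censored for r in records], dtype=bool)
    labels: list = []
    pos: dict = {}
    idx = np.empty(len(records), dtype=int)
    for i, r in enumerate(records):
        sid = r.subject_id if r.subject_id is not None else f"__anon_{r.sample_id}"
        if sid not in pos:
            pos[sid] = len(labels)
            labels.append(sid)
        idx[i] = pos[sid]
    return DesignMatrix(
        response=response,
        bound=bound,
        censored=censored,
        X=np.ones((len(records), 1)),
        columns=["intercept"],
        subject_index=idx,
        subject_labels=labels,
        block_map={"intercept": ["intercept"]},
        record_ids=[r.sample_id for r in records],
    )


def fit_intercept_only(
    dataset: StudyDataset,
    group: str,
    repeated_measures: bool = True,
    settings: McmcSettings | None = None,
    priors: PriorSpec | None = None,
    sample_type: str = "task",
) -> PosteriorChain | None:
    """Intercept-only censored fit for one task / activity / source label.

    Returns ``None`` when the group is not estimable (<3 records or no
    uncensored measurement). ``repeated_measures=True`` requests the subject
    random-intercept variant, falling back to the fixed-effect form (with a
    log notice) when too few subjects repeat.
    """
    records = [
        r
        for r in dataset.records
        if r.analyte == dataset.analyte and r.sample_type == sample_type and r.task == group
    ]
    if len(records) < 3 or all(r.censored for r in records):
        logger.warning("group %r not estimable (n=%d)", group, len(records))
        return None
    design = _intercept_design(records)
    settings = settings or DESCRIPTIVE_SETTINGS
    use_random = (
        repeated_measures and design.n_repeat_subjects() > REPEATED_MEASURES_MIN_SUBJECTS
    )
    if repeated_measures and not use_random:
        logger.warning(
            "group %r: only %d subjects with repeats; using the fixed-effect form",
            group,
            design.n_repeat_subjects(),
        )
    model = CensoredBayesLM(design, priors, random_intercept=use_random)
    return model.fit(settings, model_id=f"descriptive:{group}").chain


def lognormal_summary_from_chain(
    chain: PosteriorChain, group: str = "", n: int = 0, k: int = 0, pct_bdl: float = float("nan")
) -> LognormalSummary:
    """Per-draw GM/GSD/P95 transform of an intercept-only chain.

    On every draw P95 = GM * GSD**1.645 exactly; the reported numbers are the
    posterior medians and 95% equal-tailed intervals of the transformed draws.
    """
    mu = chain.param("intercept")
    sigma = chain.sigma_total()
    gm = np.exp(mu)
    gsd = np.exp(sigma)
    p95 = np.exp(mu + Z_P95 * sigma)
    return LognormalSummary(
        group=group,
        n=n,
        k=k,
        pct_bdl=pct_bdl,
        gm_ppb=float(np.median(gm)),
        gm_ci=credible_interval(gm, 0.95),
        gsd=float(np.median(gsd)),
        gsd_ci=credible_interval(gsd, 0.95),
        p95_ppb=float(np.median(p95)),
        p95_ci=credible_interval(p95, 0.95),
        model_kind="random_intercept" if chain.has("sigma_between") else "fixed",
    )


def stel_exceedance(records, limit_ppb: float, duration_eq: float = 15.0,
                    duration_tol: float = 1.0) -> list:
    """Per-task exceedance of a short-term limit among comparison-duration
    samples (duration within ``duration_eq +/- duration_tol`` minutes).

    Censored records count as eligible non-exceedances (the LOD sits far
    below the limit); imputed values are never used.
    """
    by_task: dict = {}
    for r in records:
        if r.sample_type != "task":
            continue
        n, ne = by_task.setdefault(r.task, (0, 0))
        if abs(r.duration_min - duration_eq) > duration_tol:
            continue
        exceed = (not r.censored) and r.concentration_ppb > limit_ppb
        by_task[r.task] = (n + 1, ne + int(exceed))
    return [
        ExceedanceSummary(task=t, limit_ppb=limit_ppb, n_eligible=n, n_exceed=ne)
        for t, (n, ne) in sorted(by_task.items())
    ]


def correlate_analytes(records_a, records_b) -> float:
    """Spearman rank correlation of log concentrations between two analytes
    measured on the same samples (matched on sample_id).

    Pairs with any censored member are excluded (count logged).
    """
    conc_b = {r.sample_id: r for r in records_b}
    pairs = []
    n_censored = 0
    for ra in records_a:
        rb = conc_b.get(ra.sample_id)
        if rb is None:
            continue
        if ra.censored or rb.censored:
            n_censored += 1
            continue
        pairs.append((math.log(ra.concentration_ppb), math.log(rb.concentration_ppb)))
    if n_censored:
        logger.info("correlate_analytes: excluded %d pairs with a censored member", n_censored)
    if len(pairs) < 3:
        raise ValueError(f"need at least 3 uncensored pairs, found {len(pairs)}")
    x, y = zip(*pairs)
    rho = spearmanr(x, y).statistic
    return float(rho)


def descriptive_table(
    dataset: StudyDataset, settings: McmcSettings | None = None, tasks=None
) -> pd.DataFrame:
    """Per-task descriptive summary table (GM, GSD, P95, %BDL, STEL counts)."""
    recs = dataset.task_records("overall")
    limit = STEL_PPB[dataset.analyte]
    exceed = {e.task: e for e in stel_exceedance(recs, limit)}
    if tasks is None:
        tasks = sorted({r.task for r in recs})
    rows = []
    for task in tasks:
        trecs = [r for r in recs if r.task == task]
        n = len(trecs)
        k = len({r.subject_id for r in trecs})
        pct_bdl = 100.0 * sum(r.censored for r in trecs) / n if n else float("nan")
        chain = fit_intercept_only(dataset, task, settings=settings)
        base = {
            "task": task,
            "n": n,
            "k": k,
            "duration_min": min((r.duration_min for r in trecs), default=float("nan")),
            "duration_max": max((r.duration_min for r in trecs), default=float("nan")),
            "pct_bdl": pct_bdl,
        }
        if chain is None:
            base.update({"gm_ppb": None, "gsd": None, "p95_ppb": None, "estimable": False})
        else:
            s = lognormal_summary_from_chain(chain, task, n, k, pct_bdl)
            base.update(
                {
                    "gm_ppb": s.gm_ppb,
                    "gsd": s.gsd,
                    "p95_ppb": s.p95_ppb,
                    "estimable": True,
                }
            )
        e = exceed.get(task)
        base["n_15min"] = e.n_eligible if e else 0
        base["n_exceed_stel"] = e.n_exceed if e else 0
        base["pct_exceed_stel"] = e.pct_exceed if e else None
        rows.append(base)
    return pd.DataFrame(rows)
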