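"""Synthetic multi-facility exposure studies with known ground truth.

The generator emulates the structure the analysis assumes: lognormal task
exposures with additive determinant effects on the log scale, per-subject
random intercepts, repeated measures within subject, per-sample limits of
detection near the analyte median, and facility-level process determinants
driven by a single latent "production scale" factor so that declared pairs
are strongly correlated (exercising the collinearity screening).

Default conditions reproduce the study design being emulated: 17 facilities,
606 task samples split 189/74/203/44/15/36/13/17/10/5 over the ten task
categories, between-task geometric-mean ratios taken from the study's task
summary table, and an overall censored fraction near 24% (diacetyl) / 27%
(2,3-pentanedione) at median LODs of 0.9 / 1.0 ppb.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm

from .datamodel import (
    ANALYTES,
    TASKS,
    DeterminantSpec,
    ExposureRecord,
    StudyDataset,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_study",
    "generate_paired_study",
    "apply_censoring",
    "expected_censored_fraction",
    "expected_study_censored_fraction",
    "default_determinant_specs",
]

#: Task sample counts of the emulated study design (sums to 606).
TASK_COUNTS = {
    "roasting": 189,
    "grinding": 74,
    "packaging": 203,
    "qc": 44,
    "flavoring": 15,
    "cleaning_machines": 36,
    "moving_beans": 13,
    "misc_production": 17,
    "misc_cafe": 10,
    "maintenance": 5,
}

#: Between-task GM ratios (log scale, reference = roasting), per analyte,
#: taken from the emulated study's descriptive task summaries.
_TASK_GM_RATIOS = {
    "diacetyl": {
        "grinding": 27.8 / 3.6,
        "packaging": 11.3 / 3.6,
        "qc": 3.9 / 3.6,
        "flavoring": 5.4 / 3.6,
        "cleaning_machines": 10.3 / 3.6,
        "moving_beans": 21.7 / 3.6,
        "misc_production": 4.7 / 3.6,
        "misc_cafe": 2.2 / 3.6,
        "maintenance": 2.0 / 3.6,
    },
    "pentanedione_23": {
        "grinding": 22.7 / 3.1,
        "packaging": 7.0 / 3.1,
        "qc": 5.5 / 3.1,
        "flavoring": 45.1 / 3.1,
        "cleaning_machines": 6.5 / 3.1,
        "moving_beans": 13.1 / 3.1,
        "misc_production": 2.7 / 3.1,
        "misc_cafe": 3.5 / 3.1,
        "maintenance": 2.0 / 3.1,
    },
}

#: Reference-task (roasting) geometric means, ppb. Calibrated analytically
#: (normal-CDF mixture over the task mix at the default spread) so the
#: expected overall censored fraction is ~0.24 / ~0.27 at the median LODs.
_REFERENCE_GM = {"diacetyl": 1.3, "pentanedione_23": 1.35}

#: Median per-sample LOD, ppb.
_LOD_MEDIAN = {"diacetyl": 0.9, "pentanedione_23": 1.0}

_PROCESS_DETERMINANTS = (
    "gev",
    "open_storage",
    "roaster_capacity_lbs",
    "grinder_capacity_lbs",
    "pct_ground_coffee",
    "flavoring_during_survey",
    "flavor_ground_coffee",
)


def default_determinant_specs() -> list:
    """The determinant dictionary the generator emits."""
    return [
        DeterminantSpec(
            name="sampled_task",
            level="sample",
            kind="categorical",
            reference="roasting",
            categories=TASKS,
            group="sample level determinants",
        ),
        DeterminantSpec(
            name="gev",
            level="process",
            kind="categorical",
            reference="no",
            categories=("no", "yes"),
            group="engineering controls determinants",
        ),
        DeterminantSpec(
            name="open_storage",
            level="process",
            kind="categorical",
            reference="none",
            categories=("none", "small", "large"),
            group="coffee storage determinants",
        ),
        DeterminantSpec(
            name="roaster_capacity_lbs",
            level="process",
            kind="continuous",
            unit_scale=250.0,
            group="amount of roasted coffee produced",
        ),
        DeterminantSpec(
            name="grinder_capacity_lbs",
            level="process",
            kind="continuous",
            unit_scale=250.0,
            group="amount of grinding performed",
        ),
        DeterminantSpec(
            name="pct_ground_coffee",
            level="process",
            kind="continuous",
            unit_scale=20.0,
            group="amount of grinding performed",
        ),
        DeterminantSpec(
            name="flavoring_during_survey",
            level="process",
            kind="categorical",
            reference="no",
            categories=("no", "yes"),
            group="flavoring process determinants",
        ),
        DeterminantSpec(
            name="flavor_ground_coffee",
            level="process",
            kind="categorical",
            reference="no",
            categories=("no", "yes"),
            nested_within=("flavoring_during_survey",),
            group="flavoring process determinants",
        ),
    ]


@dataclass
class SimulationConfig:
    """Generative parameters of one synthetic study.

    ``beta`` maps determinant name to its log-scale effect: a scalar for a
    continuous determinant (per raw unit), or a mapping category -> effect
    for a categorical one (reference omitted).
    """

    analyte: str = "diacetyl"
    n_samples: int = 606
    n_facilities: int = 17
    subjects_per_facility: tuple = (4, 12)
    samples_per_subject: tuple = (1, 8)
    task_mix: dict = field(
        default_factory=lambda: {t: c / 606 for t, c in TASK_COUNTS.items()}
    )
    intercept_log_ppb: float = math.log(_REFERENCE_GM["diacetyl"])
    beta: dict = field(
        default_factory=lambda: {
            "sampled_task": {
                t: math.log(r) for t, r in _TASK_GM_RATIOS["diacetyl"].items()
            }
        }
    )
    sigma_within: float = math.sqrt(1.4**2 - 0.4**2)
    sigma_between_subject: float = 0.4
    lod_median_ppb: float = 0.9
    lod_log_sd: float = 0.1
    process_correlation: float = 0.9
    prob_15min: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.analyte not in ANALYTES:
            raise ValueError(f"unknown analyte {self.analyte!r}")
        probs = np.array(list(self.task_mix.values()), dtype=float)
        if (probs < 0).any() or not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("task_mix probabilities must be nonnegative and sum to 1")
        if self.sigma_within < 0 or self.sigma_between_subject < 0:
            raise ValueError("standard deviations must be nonnegative")
        if not (0 <= self.process_correlation < 1):
            raise ValueError("process_correlation must be in [0, 1)")
        if self.n_samples < 1 or self.n_facilities < 1:
            raise ValueError("n_samples and n_facilities must be positive")

    @classmethod
    def default(cls, analyte: str = "diacetyl", **overrides) -> "SimulationConfig":
        """Study-design defaults for either analyte."""
        base = dict(
            analyte=analyte,
            intercept_log_ppb=math.log(_REFERENCE_GM[analyte]),
            beta={
                "sampled_task": {t: math.log(r) for t, r in _TASK_GM_RATIOS[analyte].items()}
            },
            lod_median_ppb=_LOD_MEDIAN[analyte],
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def demo_effects(cls, analyte: str = "diacetyl", **overrides) -> "SimulationConfig":
        """Defaults plus nonzero process-level effects, for end-to-end runs
        and parameter-recovery exercises."""
        cfg = cls.default(analyte, **overrides)
        beta = dict(cfg.beta)
        beta.update(
            {
                "gev": {"yes": -0.9},
                "open_storage": {"small": 0.5, "large": 0.9},
                "pct_ground_coffee": 0.02,  # per percentage point
            }
        )
        return replace(cfg, beta=beta)


@dataclass
class GroundTruth:
    """Everything the generator knew: realised effects and latent values,
    recorded before censoring was applied."""

    intercept_log_ppb: float
    beta: dict
    sigma_within: float
    sigma_between_subject: float
    subject_effects: dict
    facility_scale: dict
    uncensored_ppb: dict  # sample_id -> concentration before censoring

    def to_json(self, path) -> None:
        out = {
            "intercept_log_ppb": self.intercept_log_ppb,
            "beta": self.beta,
            "sigma_within": self.sigma_within,
            "sigma_between_subject": self.sigma_between_subject,
            "subject_effects": self.subject_effects,
            "facility_scale": self.facility_scale,
            "uncensored_ppb": self.uncensored_ppb,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(out, fh, indent=1)


def expected_censored_fraction(mu: float, sigma: float, lod: float) -> float:
    """P(ln C < ln lod) for ln C ~ Normal(mu, sigma^2)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if lod <= 0:
        raise ValueError("lod must be positive")
    return float(norm.cdf((math.log(lod) - mu) / sigma))


def expected_study_censored_fraction(config: SimulationConfig) -> float:
    """Task-mix-weighted expected censored fraction under the config
    (zero-effect process determinants assumed; LOD spread folded into the
    total log-scale spread)."""
    sigma = math.sqrt(
        config.sigma_within**2 + config.sigma_between_subject**2 + config.lod_log_sd**2
    )
    task_beta = config.beta.get("sampled_task", {})
    total = 0.0
    for task, w in config.task_mix.items():
        mu = config.intercept_log_ppb + task_beta.get(task, 0.0)
        total += w * expected_censored_fraction(mu, sigma, config.lod_median_ppb)
    return total


def _quota_counts(mix: dict, n: int) -> dict:
    """Largest-remainder allocation of n items to the task mix, so default
    configurations reproduce the design's task counts exactly."""
    items = list(mix.items())
    raw = [w * n for _, w in items]
    base = [int(math.floor(x)) for x in raw]
    short = n - sum(base)
    order = sorted(range(len(items)), key=lambda i: (raw[i] - base[i]), reverse=True)
    for i in order[:short]:
        base[i] += 1
    return {items[i][0]: base[i] for i in range(len(items))}


_DURATION_RANGE = {
    "roasting": (7, 86),
    "grinding": (2, 32),
    "packaging": (3, 55),
    "qc": (4, 18),
    "flavoring": (6, 18),
    "cleaning_machines": (5, 46),
    "moving_beans": (3, 25),
    "misc_production": (3, 29),
    "misc_cafe": (5, 16),
    "maintenance": (13, 15),
}


def _facility_processes(config: SimulationConfig, rng) -> tuple:
    """Draw facility-level process determinants from one latent scale factor."""
    lam = config.process_correlation
    noise_sd = math.sqrt(max(1.0 - lam**2, 1e-12))
    facilities = [f"F{i+1:02d}" for i in range(config.n_facilities)]
    scale = {f: float(rng.standard_normal()) for f in facilities}

    def loaded():
        return np.array([lam * scale[f] for f in facilities]) + noise_sd * rng.standard_normal(
            len(facilities)
        )

    values: dict = {f: {} for f in facilities}
    z_gev = loaded()
    z_store = loaded()
    z_rcap = loaded()
    z_gcap = loaded()
    z_pct = loaded()
    z_flav = loaded()
    z_fgrnd = rng.standard_normal(len(facilities))
    for i, f in enumerate(facilities):
        values[f]["gev"] = "yes" if z_gev[i] > 0 else "no"
        values[f]["open_storage"] = (
            "large" if z_store[i] > 0.6 else ("small" if z_store[i] > -0.4 else "none")
        )
        values[f]["roaster_capacity_lbs"] = float(np.round(np.exp(5.5 + z_rcap[i]), 1))
        values[f]["grinder_capacity_lbs"] = float(np.round(np.exp(5.0 + z_gcap[i]), 1))
        values[f]["pct_ground_coffee"] = float(
            np.round(min(max(45.0 + 22.0 * z_pct[i], 0.0), 100.0), 1)
        )
        flav = "yes" if z_flav[i] > -0.2 else "no"
        values[f]["flavoring_during_survey"] = flav
        # nested: can only flavour ground coffee where flavouring happens
        values[f]["flavor_ground_coffee"] = (
            "yes" if (flav == "yes" and z_fgrnd[i] + 0.8 * scale[f] > 0) else "no"
        )
    return facilities, scale, values


def _effect(beta: dict, name: str, value) -> float:
    eff = beta.get(name)
    if eff is None or value is None:
        return 0.0
    if isinstance(eff, dict):
        return float(eff.get(str(value), 0.0))
    return float(eff) * float(value)


def generate_study(config: SimulationConfig) -> tuple:
    """Generate one synthetic study. Deterministic under a fixed seed.

    Returns ``(StudyDataset, GroundTruth)``.
    """
    rng = np.random.default_rng(config.seed)
    facilities, scale, process_values = _facility_processes(config, rng)

    # subjects and their sample loads
    subjects = []  # (subject_id, facility_id)
    lo_s, hi_s = config.subjects_per_facility
    for f in facilities:
        for j in range(int(rng.integers(lo_s, hi_s + 1))):
            subjects.append((f"{f}-S{j+1:02d}", f))
    lo_k, hi_k = config.samples_per_subject
    loads = rng.integers(lo_k, hi_k + 1, size=len(subjects)).astype(int)
    # adjust to hit the exact sample count
    diff = config.n_samples - int(loads.sum())
    i = 0
    while diff != 0:
        j = i % len(loads)
        if diff > 0:
            loads[j] += 1
            diff -= 1
        elif loads[j] > 0:
            loads[j] -= 1
            diff += 1
        i += 1

    # task labels by exact quota, shuffled over samples
    quota = _quota_counts(config.task_mix, config.n_samples)
    task_labels = [t for t, c in quota.items() for _ in range(c)]
    rng.shuffle(task_labels)

    subject_effects = {
        sid: float(config.sigma_between_subject * rng.standard_normal())
        for sid, _ in subjects
    }

    records = []
    truth_conc: dict = {}
    pos = 0
    sample_no = 0
    for (sid, fac), k in zip(subjects, loads):
        for _ in range(k):
            task = task_labels[pos]
            pos += 1
            sample_no += 1
            det = {"sampled_task": task}
            det.update(process_values[fac])
            log_mu = config.intercept_log_ppb
            for name, value in det.items():
                log_mu += _effect(config.beta, name, value)
            log_c = log_mu + subject_effects[sid] + config.sigma_within * rng.standard_normal()
            conc = float(np.exp(log_c))
            lod = float(
                np.exp(math.log(config.lod_median_ppb) + config.lod_log_sd * rng.standard_normal())
            )
            if rng.random() < config.prob_15min:
                duration = 15.0
            else:
                lo_d, hi_d = _DURATION_RANGE.get(task, (2, 55))
                duration = float(rng.integers(lo_d, hi_d + 1))
            sample_id = f"T{sample_no:04d}"
            truth_conc[sample_id] = conc
            records.append(
                ExposureRecord(
                    sample_id=sample_id,
                    facility_id=fac,
                    subject_id=sid,
                    analyte=config.analyte,
                    concentration_ppb=conc,
                    lod_ppb=lod,
                    censored=False,
                    duration_min=duration,
                    task=task,
                    sample_type="task",
                    determinants=det,
                )
            )

    records = apply_censoring(records)
    dataset = StudyDataset(
        records=records, determinants=default_determinant_specs(), analyte=config.analyte
    )
    truth = GroundTruth(
        intercept_log_ppb=config.intercept_log_ppb,
        beta=config.beta,
        sigma_within=config.sigma_within,
        sigma_between_subject=config.sigma_between_subject,
        subject_effects=subject_effects,
        facility_scale=scale,
        uncensored_ppb=truth_conc,
    )
    return dataset, truth


def generate_paired_study(
    config_a: SimulationConfig | None = None,
    config_b: SimulationConfig | None = None,
    residual_correlation: float = 0.70,
    seed: int | None = None,
) -> tuple:
    """Generate two analytes measured on the same physical samples.

    Both analytes share the design (facilities, subjects, tasks, durations,
    per-facility process values) and their log residuals are correlated at
    ``residual_correlation``; the shared task structure adds further
    co-variation, so the default yields a Spearman correlation near 0.5
    between the two analytes' log concentrations.

    Returns ``(dataset_a, dataset_b, truth_a)``.
    """
    config_a = config_a or SimulationConfig.default("diacetyl")
    config_b = config_b or SimulationConfig.default("pentanedione_23")
    if seed is not None:
        config_a = replace(config_a, seed=seed)
    if not (-1.0 < residual_correlation < 1.0):
        raise ValueError("residual_correlation must be in (-1, 1)")

    dataset_a, truth_a = generate_study(config_a)
    rng = np.random.default_rng(config_a.seed + 1)
    rho = residual_correlation
    records_b = []
    task_beta_a = config_a.beta.get("sampled_task", {})
    task_beta_b = config_b.beta.get("sampled_task", {})
    subj_b = {
        sid: float(config_b.sigma_between_subject * rng.standard_normal())
        for sid in truth_a.subject_effects
    }
    for rec in dataset_a.records:
        conc_a = truth_a.uncensored_ppb[rec.sample_id]
        mu_a = (
            config_a.intercept_log_ppb
            + task_beta_a.get(rec.task, 0.0)
            + truth_a.subject_effects[rec.subject_id]
        )
        z_a = (math.log(conc_a) - mu_a) / config_a.sigma_within
        z_b = rho * z_a + math.sqrt(1 - rho**2) * rng.standard_normal()
        mu_b = (
            config_b.intercept_log_ppb + task_beta_b.get(rec.task, 0.0) + subj_b[rec.subject_id]
        )
        log_c = mu_b + config_b.sigma_within * z_b
        lod = float(
            np.exp(
                math.log(config_b.lod_median_ppb) + config_b.lod_log_sd * rng.standard_normal()
            )
        )
        records_b.append(
            ExposureRecord(
                sample_id=rec.sample_id,
                facility_id=rec.facility_id,
                subject_id=rec.subject_id,
                analyte=config_b.analyte,
                concentration_ppb=float(np.exp(log_c)),
                lod_ppb=lod,
                censored=False,
                duration_min=rec.duration_min,
                task=rec.task,
                sample_type="task",
                determinants=dict(rec.determinants),
            )
        )
    records_b = apply_censoring(records_b)
    dataset_b = StudyDataset(
        records=records_b,
        determinants=default_determinant_specs(),
        analyte=config_b.analyte,
    )
    return dataset_a, dataset_b, truth_a


def apply_censoring(records, lod_policy=None) -> list:
    """Flag concentrations below their per-sample LOD as left-censored.

    ``lod_policy`` may be a scalar LOD override or a callable
    ``record -> lod``. Censored records lose their concentration and keep
    the bound.
    """
    out = []
    for rec in records:
        if lod_policy is None:
            lod = rec.lod_ppb
        elif callable(lod_policy):
            lod = lod_policy(rec)
        else:
            lod = float(lod_policy)
        if lod is None or not np.isfinite(lod):
            raise ValueError(f"sample {rec.sample_id!r}: missing LOD")
        conc = rec.concentration_ppb
        if conc is None:
            if rec.censored:
                out.append(rec)
                continue
            raise ValueError(f"sample {rec.sample_id!r}: no uncensored concentration present")
        if lod > 0 and conc < lod:
            out.append(
                replace(rec, censored=True, concentration_ppb=None, lod_ppb=lod)
            )
        else:
            out.append(replace(rec, censored=False, lod_ppb=lod if lod > 0 else rec.lod_ppb))
    return out
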