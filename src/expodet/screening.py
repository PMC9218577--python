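"""Univariate determinant screening and the collinearity/nesting exclusions.

A determinant is *notable* at a given credibility level when any of its
coefficients' equal-tailed credible intervals at that level excludes zero;
screening at the 80% level decides entry into the model-averaging stage.
Pairs of screened determinants whose expanded indicator/continuous columns
correlate at |r| >= 0.5 in any cross pair (and declared nested pairs) are
barred from entering the same model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import StudyDataset, build_design_matrix, encode_determinant
from .mcmc import (
    REPEATED_MEASURES_MIN_SUBJECTS,
    CensoredBayesLM,
    McmcSettings,
    PriorSpec,
    credible_interval,
)

logger = logging.getLogger(__name__)

SCREEN_LEVELS = (0.80, 0.90, 0.95)


@dataclass
class UnivariateResult:
    """Screening result for one determinant in one task model."""

    determinant: str
    coefficients: pd.DataFrame  # one row per coefficient column
    model_kind: str
    task_filter: object

    def _any(self, level: int) -> bool:
        return bool(self.coefficients[f"notable_{level}"].any())

    @property
    def notable_80(self) -> bool:
        return self._any(80)

    @property
    def notable_90(self) -> bool:
        return self._any(90)

    @property
    def notable_95(self) -> bool:
        return self._any(95)

    @property
    def strongest_level(self) -> int:
        """0 when nothing is notable, else the highest notable level."""
        for level in (95, 90, 80):
            if self._any(level):
                return level
        return 0

    @property
    def direction(self) -> str:
        """Sign of the most extreme notable coefficient ('+', '-', or '')."""
        notable = self.coefficients[self.coefficients["notable_80"]]
        if notable.empty:
            return ""
        extreme = notable.loc[notable["median"].abs().idxmax(), "median"]
        return "+" if extreme > 0 else "-"


@dataclass
class ExclusionSet:
    """Pairs of determinants barred from the same model."""

    collinear_pairs: set = field(default_factory=set)
    nested_pairs: set = field(default_factory=set)
    correlation_matrix: pd.DataFrame | None = None

    @property
    def all_pairs(self) -> set:
        return self.collinear_pairs | self.nested_pairs

    def excludes(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.all_pairs

    def to_json_dict(self) -> dict:
        return {
            "collinear_pairs": sorted(sorted(p) for p in self.collinear_pairs),
            "nested_pairs": sorted(sorted(p) for p in self.nested_pairs),
        }


def choose_model_kind(design, task_filter) -> str:
    """Random-intercept where enough subjects repeat, else fixed — the rule
    that puts QC and flavoring task groups on the fixed-effect form."""
    if design.n_repeat_subjects() > REPEATED_MEASURES_MIN_SUBJECTS:
        return "random_intercept"
    return "fixed"


def univariate_screen(
    dataset: StudyDataset,
    determinants,
    task_filter="overall",
    settings: McmcSettings | None = None,
    priors: PriorSpec | None = None,
) -> list:
    """One single-determinant censored Bayesian fit per determinant.

    Degenerate determinants (no contrast in the filtered rows) are skipped
    with a warning. Results keep the input order.
    """
    settings = settings or McmcSettings()
    results = []
    for i, name in enumerate(determinants):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                design = build_design_matrix(dataset, [name], task_filter)
            except ValueError as exc:
                logger.warning("skipping determinant %r: %s", name, exc)
                continue
        if len(design.block_map.get(name, [])) == 0:
            logger.warning("skipping degenerate determinant %r in %r model", name, task_filter)
            continue
        kind = choose_model_kind(design, task_filter)
        model = CensoredBayesLM(design, priors, random_intercept=(kind == "random_intercept"))
        chain = model.fit(settings.with_seed(settings.seed + i), model_id=f"screen:{name}").chain
        rows = []
        for col in design.block_map[name]:
            draws = chain.param(col)
            row = {"coefficient": col, "median": float(np.median(draws))}
            for level in SCREEN_LEVELS:
                lo, hi = credible_interval(draws, level)
                tag = int(level * 100)
                row[f"ci{tag}_low"] = lo
                row[f"ci{tag}_high"] = hi
                row[f"notable_{tag}"] = bool(lo > 0 or hi < 0)
            rows.append(row)
        results.append(
            UnivariateResult(
                determinant=name,
                coefficients=pd.DataFrame(rows),
                model_kind=kind,
                task_filter=task_filter,
            )
        )
    return results


def indicator_correlations(dataset: StudyDataset, determinants, task_filter="overall") -> pd.DataFrame:
    """Pearson correlations among all expanded predictor columns.

    Each non-reference category becomes a 0/1 indicator; continuous
    determinants enter as-is. Correlations use pairwise-complete rows.
    Zero-variance columns yield NaN and are recorded as undefined.
    """
    if len(list(determinants)) < 2:
        raise ValueError("need at least 2 determinants")
    records = dataset.task_records(task_filter)
    frames = []
    for name in determinants:
        spec = dataset.spec(name)
        vals = [r.determinants.get(name) for r in records]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            enc = encode_determinant(spec, vals)
        frames.append(enc)
    wide = pd.concat(frames, axis=1)
    # disambiguate repeated labels (a determinant listed twice)
    seen: dict = {}
    cols = []
    for c in wide.columns:
        seen[c] = seen.get(c, 0) + 1
        cols.append(c if seen[c] == 1 else f"{c}#{seen[c]}")
    wide.columns = cols
    corr = wide.corr(method="pearson", min_periods=3)
    constant = [c for c in wide.columns if wide[c].nunique(dropna=True) <= 1]
    for c in constant:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
    return corr


def column_determinant(column: str) -> str:
    """Determinant name behind an expanded column label (``det[category]``)."""
    return column.split("[", 1)[0]


def build_exclusions(
    corr_matrix: pd.DataFrame, determinants, threshold: float = 0.5
) -> ExclusionSet:
    """Collinear pairs: any cross-determinant column pair with |r| >= threshold
    ("0.5 level correlation or greater"; applied to |r| since negative
    collinearity equally inflates variance). Nested pairs come from
    declarations and apply regardless of correlation.
    """
    names = [getattr(d, "name", d) for d in determinants]
    name_set = set(names)
    collinear: set = set()
    cols = list(corr_matrix.columns)
    for i, ca in enumerate(cols):
        da = column_determinant(ca)
        for cb in cols[i + 1 :]:
            db = column_determinant(cb)
            if da == db or da not in name_set or db not in name_set:
                continue
            r = corr_matrix.loc[ca, cb]
            if pd.notna(r) and abs(r) >= threshold:
                collinear.add(frozenset((da, db)))

    nested: set = set()
    spec_by_name = {getattr(d, "name", None): d for d in determinants if hasattr(d, "name")}
    for name, spec in spec_by_name.items():
        for parent in getattr(spec, "nested_within", ()):
            if parent in name_set:
                nested.add(frozenset((name, parent)))
    return ExclusionSet(
        collinear_pairs=collinear, nested_pairs=nested, correlation_matrix=corr_matrix
    )


def screen_table(results) -> pd.DataFrame:
    """Long-format screening table (one row per coefficient)."""
    rows = []
    for res in results:
        for _, c in res.coefficients.iterrows():
            row = {"determinant": res.determinant, "model_kind": res.model_kind}
            row.update(c.to_dict())
            row["direction"] = res.direction
            rows.append(row)
    return pd.DataFrame(rows)
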