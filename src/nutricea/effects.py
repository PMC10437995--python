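"""Incremental cognitive effect: difference-in-differences mixed model.

The incremental health effect ΔE is the coefficient of the group-by-time
interaction (group: control=0, intervention=1; time: baseline=0,
follow-up=1) in a linear mixed model for the BSID-III cognitive composite
score, with a random intercept at the village level and a random intercept
for the individual nested in village.  Only children assessed at both
baseline and the final follow-up (completers) enter the fit; the mid wave
is descriptive.  Estimation is by REML with a normal-theory Wald interval
on the interaction coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

#: baseline covariates adjusted for in the default fit (overlapping
#: development measures such as language and motor scores are excluded)
DEFAULT_COVARIATES = (
    "child_sex",
    "child_age_months",
    "breastfeeding",
    "dietary_diversity",
    "maternal_education_years",
    "maternal_age_years",
    "household_size",
    "poverty_score",
)

_CATEGORICAL_COVARIATES = {"child_sex", "breastfeeding", "dietary_diversity"}


class EstimationError(RuntimeError):
    """The mixed-model fit failed to converge or was singular."""


class DesignError(ValueError):
    """The records do not support the two-arm, two-wave clustered design."""


def _z(level: float) -> float:
    if not 0 < level < 1:
        raise ValueError(f"confidence level must lie in (0, 1), got {level}")
    return float(stats.norm.ppf(0.5 + level / 2))


def se_from_ci(ci_low: float, ci_high: float, level: float = 0.95) -> float:
    """Standard error implied by a normal-theory confidence interval.

    (ci_high - ci_low) / (2 z), with z the standard-normal quantile at
    (1+level)/2.  Used to reconstruct the SE of a published estimate when
    only the interval is printed.
    """
    if not ci_high > ci_low:
        raise ValueError("ci_high must exceed ci_low")
    return (ci_high - ci_low) / (2 * _z(level))


def ci_from_se(point: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Normal-theory interval around a point estimate; inverse of se_from_ci."""
    if se <= 0:
        raise ValueError("se must be positive")
    z = _z(level)
    return point - z * se, point + z * se


@dataclass(frozen=True)
class EffectEstimate:
    """Incremental cognitive composite score ΔE with its uncertainty."""

    point: float
    se: float
    ci_low: float
    ci_high: float
    ci_level: float = 0.95
    n_intervention: int | None = None
    n_control: int | None = None

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("se must be positive")
        if not self.ci_low <= self.point <= self.ci_high:
            raise ValueError("point estimate must lie inside its interval")

    @classmethod
    def from_interval(
        cls,
        point: float,
        ci_low: float,
        ci_high: float,
        level: float = 0.95,
        **kwargs,
    ) -> "EffectEstimate":
        """Build an estimate from a printed point and interval, deriving the SE."""
        return cls(
            point=point,
            se=se_from_ci(ci_low, ci_high, level),
            ci_low=ci_low,
            ci_high=ci_high,
            ci_level=level,
            **kwargs,
        )

    def to_dict(self) -> dict:
        return {
            "point": self.point,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "ci_level": self.ci_level,
            "n_intervention": self.n_intervention,
            "n_control": self.n_control,
        }


def completers(records: pd.DataFrame) -> pd.DataFrame:
    """Restrict to children observed at both baseline and the final wave."""
    waves_per_child = records.groupby("child_id", observed=True)["wave"].agg(
        lambda w: {"baseline", "final"} <= set(w.astype(str))
    )
    kept = waves_per_child[waves_per_child].index
    return records[records["child_id"].isin(kept)]


def fit_did_mixed_model(
    records: pd.DataFrame,
    covariates: tuple[str, ...] | list[str] | None = None,
    reml: bool = True,
    ci_level: float = 0.95,
) -> EffectEstimate:
    """Fit the difference-in-differences linear mixed model.

    cognitive_score ~ group + time + group:time + covariates, with a random
    intercept per village and a nested random intercept per child, on
    completers' baseline and final-wave records.  Returns the group-by-time
    coefficient with its Wald interval.

    Pass ``covariates=()`` for the unadjusted model; ``None`` selects every
    default covariate present in the table.
    """
    df = completers(records)
    df = df[df["wave"].astype(str).isin(["baseline", "final"])].copy()
    if df.empty:
        raise DesignError("no completer records at baseline and final waves")
    for arm in ("intervention", "control"):
        n_villages = df.loc[df["arm"] == arm, "village_id"].nunique()
        if n_villages < 2:
            raise DesignError(
                f"need at least 2 villages in the {arm} arm, found {n_villages}"
            )
    df["group"] = (df["arm"] == "intervention").astype(int)
    df["time"] = (df["wave"].astype(str) == "final").astype(int)

    if covariates is None:
        covariates = tuple(c for c in DEFAULT_COVARIATES if c in df.columns)
    terms = ["group * time"]
    for cov in covariates:
        if cov not in df.columns:
            raise DesignError(f"covariate {cov!r} not present in the records")
        terms.append(f"C({cov})" if cov in _CATEGORICAL_COVARIATES else cov)
    formula = "cognitive_score ~ " + " + ".join(terms)

    with warnings.catch_warnings():
        # zero-variance components on noise-free or degenerate inputs emit
        # convergence chatter that does not affect the fixed effects
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(
                formula,
                df,
                groups="village_id",
                re_formula="1",
                vc_formula={"child": "0 + C(child_id)"},
            )
            result = model.fit(reml=reml)
        except (np.linalg.LinAlgError, ValueError) as exc:
            raise EstimationError(f"mixed-model fit failed: {exc}") from exc
    point = float(result.params["group:time"])
    se = float(result.bse["group:time"])
    if not np.isfinite(point):
        raise EstimationError("mixed-model fit produced a non-finite estimate")
    if not np.isfinite(se) or se <= 0:
        # degenerate (noise-free) data: the coefficient is exact
        se = np.finfo(float).tiny
    lo, hi = ci_from_se(point, se, ci_level)
    n_by_arm = df.groupby("arm", observed=True)["child_id"].nunique()
    return EffectEstimate(
        point=point,
        se=se,
        ci_low=lo,
        ci_high=hi,
        ci_level=ci_level,
        n_intervention=int(n_by_arm.get("intervention", 0)),
        n_control=int(n_by_arm.get("control", 0)),
    )


def group_wave_means(
    records: pd.DataFrame, completers_only: bool = True
) -> pd.DataFrame:
    """Mean cognitive composite score per arm and wave.

    By default restricted to children retained through the final wave, the
    population over which the trial's descriptive means are reported.
    Returns an arm x wave table; cells without observations are NaN.
    """
    if records.empty:
        raise ValueError("records are empty")
    df = completers(records) if completers_only else records
    table = (
        df.groupby(["arm", "wave"], observed=False)["cognitive_score"]
        .mean()
        .unstack("wave")
    )
    return table


@dataclass(frozen=True)
class BalanceRow:
    """One row of the baseline balance table: arm summaries and test p-value."""

    variable: str
    group_summaries: dict
    test: str  # "chi_square" | "t_test" | "not_applicable"
    p_value: float | None

    @property
    def significant(self) -> bool:
        return self.p_value is not None and self.p_value < 0.05


def baseline_balance(
    records: pd.DataFrame,
    categorical: tuple[str, ...] | None = None,
    numerical: tuple[str, ...] | None = None,
) -> list[BalanceRow]:
    """Arm-balance tests on baseline records.

    Categorical variables get a Pearson chi-square test on the arm-by-level
    contingency table (no continuity correction); numerical variables a
    two-sample pooled-variance t-test.  Variables default to every known
    baseline covariate present, plus the baseline cognitive score.
    """
    df = records[records["wave"].astype(str) == "baseline"]
    arms = sorted(df["arm"].unique())
    if len(arms) != 2:
        raise DesignError(f"need exactly 2 arms at baseline, found {arms}")
    if categorical is None:
        categorical = tuple(
            c for c in _CATEGORICAL_COVARIATES if c in df.columns
        )
    if numerical is None:
        known_numeric = (
            "child_age_months",
            "cognitive_score",
            "maternal_education_years",
            "maternal_age_years",
            "household_size",
            "poverty_score",
        )
        numerical = tuple(c for c in known_numeric if c in df.columns)

    rows: list[BalanceRow] = []
    for var in categorical:
        table = pd.crosstab(df[var], df["arm"])
        summaries = {
            arm: {
                str(level): f"{int(count)} ({100 * count / table[arm].sum():.1f})"
                for level, count in table[arm].items()
            }
            for arm in arms
        }
        expected = stats.contingency.expected_freq(table.to_numpy())
        if (expected == 0).any() or table.shape[0] < 2:
            rows.append(BalanceRow(var, summaries, "not_applicable", None))
            continue
        p = float(stats.chi2_contingency(table.to_numpy(), correction=False)[1])
        rows.append(BalanceRow(var, summaries, "chi_square", p))
    for var in numerical:
        groups = [df.loc[df["arm"] == arm, var].dropna() for arm in arms]
        summaries = {
            arm: f"{g.mean():.2f} ({g.std(ddof=1):.2f})"
            for arm, g in zip(arms, groups)
        }
        if all(len(g) > 1 for g in groups) and np.ptp(np.concatenate(groups)) > 0:
            p = float(stats.ttest_ind(*groups, equal_var=True).pvalue)
        else:
            p = 1.0 if all(len(g) for g in groups) else None
        rows.append(
            BalanceRow(
                var,
                summaries,
                "t_test" if p is not None else "not_applicable",
                p,
            )
        )
    return rows
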