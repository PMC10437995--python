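"""Synthetic cluster-randomized trial generator.

Emulates a two-armed pragmatic cluster-RCT of a maternal nutrition education
intervention in which mother/child dyads are enrolled at child age 6-8
months (263 intervention / 248 control), followed up at 12-16 and 20-24
months, and assessed with the BSID-III cognitive composite score.  Scores
follow a linear mixed model with a village-level random intercept, an
individual random intercept, and i.i.d. residual noise around arm-by-wave
means; the difference-in-differences contrast of the four baseline/final
cell means equals the configured true effect exactly.  Covariates are drawn
independently from the trial's reported baseline marginals and do not affect
the score, so a correctly specified analysis should attribute the whole
group-by-time contrast to the intervention.

Trial data are represented as a long-format :class:`pandas.DataFrame` with
one row per child-wave observation (see :data:`TRIAL_COLUMNS`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

WAVES = ("baseline", "mid", "final")

#: child age (months) midpoints for the three assessment waves (6-8, 12-16, 20-24)
WAVE_AGES = {"baseline": 7, "mid": 14, "final": 22}

#: core schema of the long-format trial table; covariate columns follow
TRIAL_COLUMNS = (
    "child_id",
    "village_id",
    "arm",
    "wave",
    "age_months",
    "cognitive_score",
)

COVARIATE_COLUMNS = (
    "child_sex",
    "child_age_months",
    "breastfeeding",
    "dietary_diversity",
    "maternal_education_years",
    "maternal_age_years",
    "household_size",
    "poverty_score",
)

# Baseline covariate marginals by arm (intervention, control): categorical
# probabilities and normal (mean, sd) pairs from the trial's baseline table.
_CAT_MARGINALS = {
    "child_sex": (["male", "female"], {"intervention": [0.529, 0.471], "control": [0.496, 0.504]}),
    "breastfeeding": (
        ["on_demand", "le_8_per_day"],
        {"intervention": [0.649, 0.351], "control": [0.738, 0.262]},
    ),
    "dietary_diversity": (
        ["low", "medium", "high"],
        {"intervention": [0.567, 0.316, 0.117], "control": [0.677, 0.263, 0.060]},
    ),
}
_NUM_MARGINALS = {
    "child_age_months": {"intervention": (7.39, 0.83), "control": (7.26, 0.91)},
    "maternal_education_years": {"intervention": (4.85, 2.82), "control": (4.92, 2.75)},
    "maternal_age_years": {"intervention": (26.17, 5.92), "control": (26.98, 6.5)},
    "household_size": {"intervention": (5.47, 2.08), "control": (5.48, 2.09)},
    "poverty_score": {"intervention": (47.84, 11.65), "control": (47.61, 11.38)},
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Design parameters of the synthetic trial.

    Defaults mirror the emulated study: enrolment 263/248, retention
    227/196, baseline cognitive composite means 102.37 (intervention) and
    103.42 (control) with total SD 13, a true group-by-time effect of 16.11
    score units, and a control-arm drift of -4.05 units from baseline to the
    final wave (103.42 -> 99.37).  The mid wave (means 110.50 / 103.31) is
    descriptive only and excluded from effect estimation downstream.

    The variance components (village 3.0, individual 7.0, residual 10.55)
    are a stand-in decomposition chosen so that their squares sum to the
    observed baseline variance 13^2 (within 1%) with a small positive
    village-level intra-cluster correlation (~0.05); the true cluster count
    and ICC of the emulated trial are not reported, so 20 villages (10 per
    arm) is likewise a configurable stand-in.
    """

    n_intervention: int = 263
    n_control: int = 248
    n_villages: int = 20
    retained_intervention: int = 227
    retained_control: int = 196
    baseline_mean_intervention: float = 102.37
    baseline_mean_control: float = 103.42
    baseline_sd: float = 13.0
    true_effect: float = 16.11
    control_followup_drift: float = -4.05
    mid_mean_intervention: float = 110.50
    mid_mean_control: float = 103.31
    sd_village: float = 3.0
    sd_individual: float = 7.0
    sd_residual: float = 10.55
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_villages < 2 or self.n_villages % 2:
            raise ValueError("n_villages must be an even number >= 2")
        if self.retained_intervention > self.n_intervention:
            raise ValueError("retained_intervention exceeds enrolment")
        if self.retained_control > self.n_control:
            raise ValueError("retained_control exceeds enrolment")
        if min(self.retained_intervention, self.retained_control) < 1:
            raise ValueError("retained counts must be positive")
        for name in ("sd_village", "sd_individual", "sd_residual", "baseline_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def wave_means(self, arm: str) -> dict[str, float]:
        """Arm-specific population means per wave.

        The final-wave intervention mean is constructed so that the
        difference-in-differences contrast of the four baseline/final cell
        means equals ``true_effect`` exactly.
        """
        control_final = self.baseline_mean_control + self.control_followup_drift
        if arm == "control":
            return {
                "baseline": self.baseline_mean_control,
                "mid": self.mid_mean_control,
                "final": control_final,
            }
        return {
            "baseline": self.baseline_mean_intervention,
            "mid": self.mid_mean_intervention,
            "final": self.baseline_mean_intervention
            + self.control_followup_drift
            + self.true_effect,
        }


def _draw_covariates(rng: np.random.Generator, arm: str, n: int) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {}
    for name, (levels, probs) in _CAT_MARGINALS.items():
        cols[name] = rng.choice(levels, size=n, p=np.asarray(probs[arm]) / sum(probs[arm]))
    for name, params in _NUM_MARGINALS.items():
        mean, sd = params[arm]
        draw = rng.normal(mean, sd, size=n)
        if name in ("household_size",):
            draw = np.clip(np.round(draw), 1, None)
        cols[name] = draw
    return pd.DataFrame(cols)


def generate_trial(config: SyntheticConfig) -> pd.DataFrame:
    """Generate the full enrolled cohort, three waves per child.

    Deterministic given ``config.seed``.  Villages are split half/half
    between arms and children assigned round-robin within their arm, so the
    randomisation is at the village level and every village is single-arm.
    """
    rng = np.random.default_rng(config.seed)
    half = config.n_villages // 2
    village_ids = [f"V{k:03d}" for k in range(config.n_villages)]
    arm_villages = {
        "intervention": village_ids[:half],
        "control": village_ids[half:],
    }
    village_eff = dict(
        zip(village_ids, rng.normal(0.0, config.sd_village, config.n_villages))
    )

    frames = []
    child_counter = 0
    for arm, n_arm in (
        ("intervention", config.n_intervention),
        ("control", config.n_control),
    ):
        vils = arm_villages[arm]
        child_ids = [f"C{child_counter + j:04d}" for j in range(n_arm)]
        child_counter += n_arm
        villages = [vils[j % len(vils)] for j in range(n_arm)]
        child_eff = rng.normal(0.0, config.sd_individual, n_arm)
        covs = _draw_covariates(rng, arm, n_arm)
        means = config.wave_means(arm)
        for wave in WAVES:
            resid = rng.normal(0.0, config.sd_residual, n_arm)
            score = (
                means[wave]
                + np.array([village_eff[v] for v in villages])
                + child_eff
                + resid
            )
            frame = pd.DataFrame(
                {
                    "child_id": child_ids,
                    "village_id": villages,
                    "arm": arm,
                    "wave": wave,
                    "age_months": WAVE_AGES[wave],
                    "cognitive_score": score,
                }
            )
            frames.append(pd.concat([frame, covs.set_index(frame.index)], axis=1))
    out = pd.concat(frames, ignore_index=True)
    wave_order = pd.CategoricalDtype(WAVES, ordered=True)
    out["wave"] = out["wave"].astype(wave_order)
    return out.sort_values(["child_id", "wave"], ignore_index=True)


def apply_attrition(records: pd.DataFrame, config: SyntheticConfig) -> pd.DataFrame:
    """Drop children missing-completely-at-random down to the retained counts.

    Children selected for dropout keep only their baseline record; exactly
    ``retained_intervention`` and ``retained_control`` children retain
    mid- and final-wave records.  Deterministic given ``config.seed`` (an
    independent stream from :func:`generate_trial`, so the same cohort can
    be re-used under different attrition draws only by changing the seed).
    """
    rng = np.random.default_rng([config.seed, 1])
    keep_parts = []
    for arm, retained in (
        ("intervention", config.retained_intervention),
        ("control", config.retained_control),
    ):
        children = np.sort(records.loc[records["arm"] == arm, "child_id"].unique())
        if retained > len(children):
            raise ValueError(
                f"retained count {retained} exceeds {len(children)} enrolled "
                f"children in the {arm} arm"
            )
        kept = rng.choice(children, size=retained, replace=False)
        keep_parts.append(pd.Index(kept))
    kept_children = keep_parts[0].union(keep_parts[1])
    mask = records["child_id"].isin(kept_children) | (records["wave"] == "baseline")
    return records.loc[mask].reset_index(drop=True)


def simulate_trial(config: SyntheticConfig | None = None) -> pd.DataFrame:
    """Generate the enrolled cohort and apply attrition in one call."""
    config = config or SyntheticConfig()
    return apply_attrition(generate_trial(config), config)


def write_trial_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def read_trial_csv(path) -> pd.DataFrame:
    """Read a long-format trial CSV, restoring the ordered wave dtype."""
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns) - {"age_months"}
    if missing:
        raise ValueError(f"trial table is missing columns: {sorted(missing)}")
    df["wave"] = df["wave"].astype(pd.CategoricalDtype(WAVES, ordered=True))
    return df
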