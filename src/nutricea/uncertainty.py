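"""Sensitivity analyses: one-way (tornado), probabilistic (Monte Carlo), CEAC.

One-way deterministic sensitivity analysis moves one parameter at a time to
its low and high bound — cost categories by multiplicative factors
(personnel 0.5–1.2, the other categories 0.8–1.2), the incremental effect
to its 95% CI bounds — and records the ICER at each bound.

The probabilistic sensitivity analysis draws the incremental effect from
Normal(point, SE) and each per-child category cost from an independent
uniform over its one-way range, 1000 draws by default, and summarises the
joint (ΔC, ΔE) distribution: per-sample ICERs over north-east-quadrant
draws, a 2.5–97.5 percentile interval, quadrant counts, and the
cost-effectiveness acceptability curve P(λ·ΔE − ΔC > 0) over a
willingness-to-pay grid.  An independent semi-analytic evaluation of the
same acceptability probability (normal × sum-of-uniforms convolution) is
provided for cross-checking the Monte Carlo results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cea import Quadrant, classify_quadrant, icer, nmb
from .costs import CATEGORIES, CostSummary, apply_multipliers
from .effects import EffectEstimate

#: default multiplier ranges for the cost categories: personnel may halve
#: at scale but rise 20%; all other categories vary ±20%
DEFAULT_COST_RANGES: dict[str, tuple[float, float]] = {
    "personnel": (0.5, 1.2),
    "materials_other": (0.8, 1.2),
    "capacity_building": (0.8, 1.2),
    "capital": (0.8, 1.2),
}

#: default willingness-to-pay grid, USD per score unit
DEFAULT_WTP_GRID: np.ndarray = np.arange(0.0, 30.5, 0.5)

EFFECT_PARAMETER = "effect"


@dataclass(frozen=True)
class DSAParameter:
    """One tornado parameter: a cost-category multiplier or the absolute effect."""

    name: str
    reference: float
    low: float
    high: float
    kind: str  # "multiplier" | "absolute"

    def __post_init__(self) -> None:
        if not self.low <= self.reference <= self.high:
            raise ValueError(
                f"{self.name}: bounds must satisfy low <= reference <= high, "
                f"got ({self.low}, {self.reference}, {self.high})"
            )
        if self.kind not in ("multiplier", "absolute"):
            raise ValueError(f"unknown parameter kind {self.kind!r}")


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low: float
    high: float
    icer_at_low: float
    icer_at_high: float

    @property
    def span(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def default_dsa_parameters(
    effect: EffectEstimate,
    cost_ranges: Mapping[str, tuple[float, float]] | None = None,
) -> list[DSAParameter]:
    """The five standard tornado parameters: four cost categories + effect."""
    ranges = dict(DEFAULT_COST_RANGES)
    if cost_ranges:
        ranges.update(cost_ranges)
    params = [
        DSAParameter(cat, 1.0, *ranges[cat], kind="multiplier") for cat in CATEGORIES
    ]
    params.append(
        DSAParameter(
            EFFECT_PARAMETER, effect.point, effect.ci_low, effect.ci_high, "absolute"
        )
    )
    return params


def _icer_value(delta_c: float, delta_e: float) -> float:
    res = icer(delta_c, delta_e)
    if res.icer is None:
        raise ValueError(
            f"ICER undefined outside the NE quadrant (ΔC={delta_c}, ΔE={delta_e})"
        )
    return res.icer


def one_way_dsa(
    base: CostSummary,
    effect: EffectEstimate,
    params: Sequence[DSAParameter] | None = None,
) -> list[TornadoEntry]:
    """Tornado analysis: ICER with each parameter at its low/high bound.

    All other parameters stay at reference.  Entries are sorted by
    decreasing ICER span, ties broken alphabetically.
    """
    if params is None:
        params = default_dsa_parameters(effect)
    entries = []
    for p in params:
        if p.kind == "multiplier":
            if p.name not in CATEGORIES:
                raise ValueError(f"unknown cost category {p.name!r}")
            lo_c = apply_multipliers(base, {p.name: p.low}).per_child_total
            hi_c = apply_multipliers(base, {p.name: p.high}).per_child_total
            entry = TornadoEntry(
                p.name,
                p.low,
                p.high,
                _icer_value(lo_c, effect.point),
                _icer_value(hi_c, effect.point),
            )
        elif p.name == EFFECT_PARAMETER:
            entry = TornadoEntry(
                p.name,
                p.low,
                p.high,
                _icer_value(base.per_child_total, p.low),
                _icer_value(base.per_child_total, p.high),
            )
        else:
            raise ValueError(f"unrecognised DSA parameter {p.name!r}")
        entries.append(entry)
    return sorted(entries, key=lambda e: (-e.span, e.parameter))


def tornado_table(entries: Sequence[TornadoEntry], rounding: int = 2) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "low": [e.low for e in entries],
            "high": [e.high for e in entries],
            "icer_low": [round(e.icer_at_low, rounding) for e in entries],
            "icer_high": [round(e.icer_at_high, rounding) for e in entries],
            "span": [round(e.span, rounding) for e in entries],
        }
    )


@dataclass(frozen=True)
class PSAConfig:
    """Monte Carlo settings: draw count, seed, and cost multiplier ranges.

    The effect distribution is Normal(ΔE point, ΔE se) taken from the
    :class:`EffectEstimate`; cost distributions are independent uniforms on
    the one-way ranges, applied as multipliers to per-child category costs.
    """

    n_samples: int = 1000
    seed: int = 0
    cost_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COST_RANGES)
    )

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for cat, (lo, hi) in self.cost_ranges.items():
            if cat not in CATEGORIES:
                raise ValueError(f"unknown cost category {cat!r}")
            if not lo <= hi:
                raise ValueError(f"{cat}: uniform bounds must be ordered")


@dataclass(frozen=True)
class PSAResult:
    """PSA draws and their summaries.

    ``samples`` has one row per draw: delta_e, delta_c, icer (NaN outside
    the NE quadrant), quadrant.  ``icer_mean`` is the mean of per-sample
    ICERs over NE draws; ``icer_ratio_of_means`` divides the mean ΔC by the
    mean ΔE instead — the two summaries bracket the conventional choices.
    """

    samples: pd.DataFrame
    icer_mean: float
    icer_ratio_of_means: float
    icer_interval: tuple[float, float]
    quadrant_counts: dict[str, int]
    n_excluded_from_icer: int

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def run_psa(
    config: PSAConfig, base: CostSummary, effect: EffectEstimate
) -> PSAResult:
    """Propagate parameter uncertainty by independent Monte Carlo sampling.

    Deterministic given ``config.seed``.  Draws with ΔE ≤ 0 (or outside the
    NE quadrant) are excluded from ICER summaries — a ratio across
    quadrants is meaningless — but retained in the samples, quadrant
    counts, and any CEAC built from them.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    delta_e = rng.normal(effect.point, effect.se, n)
    delta_c = np.zeros(n)
    for cat in CATEGORIES:  # fixed order keeps the stream reproducible
        lo, hi = config.cost_ranges.get(cat, (1.0, 1.0))
        delta_c += base.per_child_by_category[cat] * rng.uniform(lo, hi, n)
    quadrants = np.array(
        [classify_quadrant(c, e).value for c, e in zip(delta_c, delta_e)]
    )
    ne = (delta_e > 0) & (delta_c >= 0)
    icers = np.where(ne, delta_c / np.where(delta_e > 0, delta_e, np.nan), np.nan)
    samples = pd.DataFrame(
        {
            "draw": np.arange(n),
            "delta_e": delta_e,
            "delta_c": delta_c,
            "icer": icers,
            "quadrant": quadrants,
        }
    )
    ne_icers = icers[ne]
    if ne_icers.size == 0:
        raise ValueError("no NE-quadrant draws: ICER summaries are undefined")
    counts = {q.value: int((quadrants == q.value).sum()) for q in Quadrant}
    return PSAResult(
        samples=samples,
        icer_mean=float(np.mean(ne_icers)),
        icer_ratio_of_means=float(np.mean(delta_c) / np.mean(delta_e)),
        icer_interval=(
            float(np.percentile(ne_icers, 2.5)),
            float(np.percentile(ne_icers, 97.5)),
        ),
        quadrant_counts=counts,
        n_excluded_from_icer=int(n - ne.sum()),
    )


@dataclass(frozen=True)
class CEACPoint:
    wtp: float
    probability: float


def ceac(result: PSAResult, wtp_grid: Sequence[float] | None = None) -> list[CEACPoint]:
    """Cost-effectiveness acceptability curve over a willingness-to-pay grid.

    At each λ, the probability is the share of PSA draws with strictly
    positive net monetary benefit λ·ΔE − ΔC (a draw exactly on the
    boundary counts as not cost-effective).
    """
    if wtp_grid is None:
        wtp_grid = DEFAULT_WTP_GRID
    de = result.samples["delta_e"].to_numpy()
    dc = result.samples["delta_c"].to_numpy()
    points = []
    for wtp in wtp_grid:
        if wtp < 0:
            raise ValueError(f"willingness to pay must be >= 0, got {wtp}")
        points.append(CEACPoint(float(wtp), float(np.mean(wtp * de - dc > 0))))
    return points


def ceac_table(points: Sequence[CEACPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {"wtp": [p.wtp for p in points], "probability": [p.probability for p in points]}
    )


def ce_plane(result: PSAResult) -> tuple[pd.DataFrame, dict[str, int]]:
    """Scatter table of (ΔE, ΔC) draws with quadrant labels, plus counts."""
    if result.samples.empty:
        raise ValueError("PSA result holds no samples")
    scatter = result.samples[["draw", "delta_e", "delta_c", "quadrant"]].copy()
    return scatter, dict(result.quadrant_counts)


def ceac_probability_analytic(
    wtp: float,
    base: CostSummary,
    effect: EffectEstimate,
    cost_ranges: Mapping[str, tuple[float, float]] | None = None,
    grid_step: float = 0.01,
) -> float:
    """P(λ·ΔE − ΔC > 0) by numerical convolution, without Monte Carlo.

    ΔC is a sum of independent uniforms (per-child category cost times its
    multiplier range); its density is built by convolving the uniform
    densities on a fine grid, then integrated against the normal survival
    function of λ·ΔE.  Serves as an independent oracle for the Monte Carlo
    CEAC.
    """
    if wtp < 0:
        raise ValueError("willingness to pay must be >= 0")
    ranges = dict(DEFAULT_COST_RANGES)
    if cost_ranges:
        ranges.update(cost_ranges)
    supports = []
    for cat in CATEGORIES:
        c = base.per_child_by_category[cat]
        lo, hi = ranges.get(cat, (1.0, 1.0))
        supports.append((c * lo, c * hi))
    degenerate_shift = sum(lo for lo, hi in supports if hi - lo < grid_step)
    widths = [(lo, hi) for lo, hi in supports if hi - lo >= grid_step]

    if not widths:  # all categories (near) fixed: ΔC is a constant
        c_total = degenerate_shift
        if wtp == 0:
            return float(0.0 < -c_total)
        z = (wtp * effect.point - c_total) / (wtp * effect.se)
        return float(stats.norm.cdf(z))

    # density of the sum of the non-degenerate uniforms, by FFT-free convolution
    density = None
    start = 0.0
    for lo, hi in widths:
        n_pts = max(int(np.ceil((hi - lo) / grid_step)), 2)
        u = np.full(n_pts, 1.0 / (hi - lo))
        if density is None:
            density = u
        else:
            density = np.convolve(density, u) * grid_step
        start += lo
    grid = start + degenerate_shift + grid_step * np.arange(density.size)
    density = density / (density.sum() * grid_step)  # renormalise truncation error

    if wtp == 0:
        return float(np.sum(density[grid < 0]) * grid_step)
    z = (wtp * effect.point - grid) / (wtp * effect.se)
    return float(np.sum(density * stats.norm.cdf(z)) * grid_step)
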