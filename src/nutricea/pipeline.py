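"""End-to-end orchestration: config, pipeline stages, and report files.

The pipeline chains the analysis stages — cost summary, incremental effect
(fitted from trial records or supplied as a published point + interval),
deterministic ICER, tornado, PSA, CEAC — and writes deterministic CSV/JSON
reports plus optional figures.  Two runs with the same config produce
byte-identical tables.
"""

from __future__ import annotations

import json
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cea import CEAResult, icer
from .costs import (
    CostSummary,
    load_ledger,
    packaged_ledger_path,
    summarize_costs,
)
from .effects import EffectEstimate, fit_did_mixed_model, group_wave_means
from .simulate import SyntheticConfig, read_trial_csv, simulate_trial
from .uncertainty import (
    DEFAULT_COST_RANGES,
    DEFAULT_WTP_GRID,
    PSAConfig,
    PSAResult,
    CEACPoint,
    TornadoEntry,
    ceac,
    ceac_table,
    default_dsa_parameters,
    one_way_dsa,
    run_psa,
    tornado_table,
)


class ConfigError(ValueError):
    """The analysis configuration failed validation."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Validated configuration of a full pipeline run.

    Exactly one effect source is used: an explicit ``effect`` block
    (point, ci_low, ci_high) mirroring a published estimate, a
    ``trial_data_path`` to fit from records on disk, or a ``synthetic``
    block to simulate records first.  When several are given, precedence is
    effect > trial_data_path > synthetic.
    """

    ledger_path: Path | None = None  # None selects the packaged ledger
    n_children: int = 227
    total_override: float | None = None
    effect: Mapping[str, float] | None = None
    trial_data_path: Path | None = None
    synthetic: Mapping[str, Any] | None = None
    covariates: tuple[str, ...] | None = None
    dsa_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COST_RANGES)
    )
    psa_n_samples: int = 1000
    seed: int = 0
    wtp_grid: tuple[float, ...] = tuple(DEFAULT_WTP_GRID)
    output_dir: Path = Path("nutricea_output")
    rounding: int = 2
    make_figures: bool = False

    def __post_init__(self) -> None:
        if self.n_children <= 0:
            raise ConfigError("n_children must be positive")
        if self.psa_n_samples < 1:
            raise ConfigError("psa.n_samples must be >= 1")
        if self.rounding < 0:
            raise ConfigError("report_rounding must be >= 0")
        if any(w < 0 for w in self.wtp_grid):
            raise ConfigError("wtp_grid values must be >= 0")
        if self.effect is not None:
            missing = {"point", "ci_low", "ci_high"} - set(self.effect)
            if missing:
                raise ConfigError(f"effect block is missing keys: {sorted(missing)}")
        elif self.trial_data_path is None and self.synthetic is None:
            raise ConfigError(
                "one of effect, trial_data_path or synthetic must be given"
            )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} must be a YAML mapping")
        return cls.from_mapping({**raw, **overrides}, base_dir=Path(path).parent)

    @classmethod
    def from_mapping(
        cls, raw: Mapping[str, Any], base_dir: Path | None = None
    ) -> "AnalysisConfig":
        known = {
            "ledger_path",
            "n_children",
            "total_override",
            "effect",
            "trial_data_path",
            "synthetic",
            "covariates",
            "dsa_ranges",
            "psa",
            "seed",
            "wtp_grid",
            "output_dir",
            "rounding",
            "make_figures",
        }
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")

        def _resolve(p):
            if p is None:
                return None
            p = Path(p)
            if base_dir is not None and not p.is_absolute():
                p = base_dir / p
            return p

        ledger_path = _resolve(raw.get("ledger_path"))
        if ledger_path is not None and not ledger_path.exists():
            raise ConfigError(f"ledger_path does not exist: {ledger_path}")
        trial_path = _resolve(raw.get("trial_data_path"))
        if trial_path is not None and not trial_path.exists():
            raise ConfigError(f"trial_data_path does not exist: {trial_path}")
        psa_block = raw.get("psa") or {}
        dsa = {k: tuple(v) for k, v in (raw.get("dsa_ranges") or DEFAULT_COST_RANGES).items()}
        wtp = raw.get("wtp_grid")
        if isinstance(wtp, Mapping):
            wtp = tuple(
                np.arange(wtp.get("start", 0.0), wtp.get("stop", 30.0) + 1e-9, wtp.get("step", 0.5))
            )
        elif wtp is not None:
            wtp = tuple(float(w) for w in wtp)
        else:
            wtp = tuple(DEFAULT_WTP_GRID)
        covs = raw.get("covariates")
        return cls(
            ledger_path=ledger_path,
            n_children=int(raw.get("n_children", 227)),
            total_override=raw.get("total_override"),
            effect=raw.get("effect"),
            trial_data_path=trial_path,
            synthetic=raw.get("synthetic"),
            covariates=tuple(covs) if covs is not None else None,
            dsa_ranges=dsa,
            psa_n_samples=int(psa_block.get("n_samples", 1000)),
            seed=int(psa_block.get("seed", raw.get("seed", 0))),
            wtp_grid=wtp,
            output_dir=_resolve(raw.get("output_dir")) or Path("nutricea_output"),
            rounding=int(raw.get("rounding", 2)),
            make_figures=bool(raw.get("make_figures", False)),
        )


@dataclass(frozen=True)
class ReportBundle:
    """Everything a pipeline run computed, ready for rendering."""

    config: AnalysisConfig
    costs: CostSummary
    effect: EffectEstimate
    deterministic: CEAResult
    tornado: list[TornadoEntry]
    psa: PSAResult
    ceac_points: list[CEACPoint]
    group_means: pd.DataFrame | None
    log: dict


def _resolve_effect(config: AnalysisConfig) -> tuple[EffectEstimate, pd.DataFrame | None]:
    if config.effect is not None:
        eff = config.effect
        return (
            EffectEstimate.from_interval(
                point=float(eff["point"]),
                ci_low=float(eff["ci_low"]),
                ci_high=float(eff["ci_high"]),
                level=float(eff.get("ci_level", 0.95)),
            ),
            None,
        )
    if config.trial_data_path is not None:
        records = read_trial_csv(config.trial_data_path)
    else:
        syn = dict(config.synthetic or {})
        syn.setdefault("seed", config.seed)
        records = simulate_trial(SyntheticConfig(**syn))
    return fit_did_mixed_model(records, covariates=config.covariates), records


def run_pipeline(config: AnalysisConfig) -> ReportBundle:
    """Execute every stage and return the assembled results.

    Stage order: costs → effect → deterministic ICER → tornado → PSA →
    CEAC.  Any stage failure propagates with its stage named.
    """
    t0 = time.perf_counter()
    timings: dict[str, float] = {}

    def _stage(name, fn):
        t = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        timings[name] = round(time.perf_counter() - t, 4)
        return out

    costs = _stage(
        "costs",
        lambda: summarize_costs(
            load_ledger(config.ledger_path or packaged_ledger_path()),
            n_children=config.n_children,
            total_override=config.total_override,
        ),
    )
    effect, records = _stage("effect", lambda: _resolve_effect(config))
    means = group_wave_means(records) if records is not None else None
    deterministic = _stage(
        "deterministic_cea", lambda: icer(costs.per_child_total, effect.point)
    )
    tornado = _stage(
        "tornado",
        lambda: one_way_dsa(
            costs, effect, default_dsa_parameters(effect, config.dsa_ranges)
        ),
    )
    psa = _stage(
        "psa",
        lambda: run_psa(
            PSAConfig(
                n_samples=config.psa_n_samples,
                seed=config.seed,
                cost_ranges=config.dsa_ranges,
            ),
            costs,
            effect,
        ),
    )
    ceac_points = _stage("ceac", lambda: ceac(psa, config.wtp_grid))
    log = {
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "n_psa_samples": config.psa_n_samples,
        "timings_s": timings,
        "total_s": round(time.perf_counter() - t0, 4),
    }
    return ReportBundle(
        config=config,
        costs=costs,
        effect=effect,
        deterministic=deterministic,
        tornado=tornado,
        psa=psa,
        ceac_points=ceac_points,
        group_means=means,
        log=log,
    )


def render_reports(bundle: ReportBundle, output_dir: str | Path | None = None) -> list[Path]:
    """Write the bundle as CSV/JSON tables (and figures when configured).

    Returns the list of files written.  Monetary figures are rounded to the
    configured number of decimals at this reporting boundary only.
    """
    config = bundle.config
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    r = config.rounding
    written: list[Path] = []

    def _write_json(name: str, payload) -> None:
        path = out / name
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        written.append(path)

    costs = bundle.costs
    _write_json(
        "costs.json",
        {
            "category_totals": {c: round(v, r) for c, v in costs.category_totals.items()},
            "total": round(costs.total, r),
            "n_children": costs.n_children,
            "per_child_total": round(costs.per_child_total, r),
            "per_child_by_category": {
                c: round(v, r) for c, v in costs.per_child_by_category.items()
            },
            "category_shares_pct": {
                c: round(100 * s) for c, s in costs.category_shares.items()
            },
        },
    )
    _write_json("effect.json", bundle.effect.to_dict())
    _write_json("cea.json", bundle.deterministic.to_dict(rounding=r))

    tornado_path = out / "tornado.csv"
    tornado_table(bundle.tornado, rounding=r).to_csv(tornado_path, index=False)
    written.append(tornado_path)

    if bundle.psa.n_samples:
        psa_path = out / "psa_samples.csv"
        bundle.psa.samples.round(6).to_csv(psa_path, index=False)
        written.append(psa_path)
        lo, hi = bundle.psa.icer_interval
        _write_json(
            "psa_summary.json",
            {
                "icer_mean": round(bundle.psa.icer_mean, r),
                "icer_ratio_of_means": round(bundle.psa.icer_ratio_of_means, r),
                "icer_interval": [round(lo, r), round(hi, r)],
                "quadrant_counts": bundle.psa.quadrant_counts,
                "n_excluded_from_icer": bundle.psa.n_excluded_from_icer,
            },
        )
        ceac_path = out / "ceac.csv"
        ceac_table(bundle.ceac_points).to_csv(ceac_path, index=False)
        written.append(ceac_path)

    if bundle.group_means is not None:
        means_path = out / "group_wave_means.csv"
        bundle.group_means.round(r).to_csv(means_path)
        written.append(means_path)

    _write_json("run_log.json", bundle.log)

    if config.make_figures:
        from .plots import render_figures

        written.extend(render_figures(bundle, out))
    return written
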