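"""Monte Carlo experiment driver and distribution summaries.

One call to :func:`run` draws a single shared parameter matrix and
evaluates every requested scenario on it (common random numbers), so that
cross-scenario comparisons are paired and differences between stoves are
not inflated by independent sampling noise.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import Catalog
from .model import (
    BREAKDOWN_COLUMNS,
    CostBenefitBreakdown,
    DEFAULT_CONFIG,
    ModelConfig,
    Scenario,
    evaluate,
)
from .sampler import DrawMatrix, sample

__all__ = ["SimulationSummary", "SimulationRun", "run", "cdf_table", "catalog_hash"]

logger = logging.getLogger(__name__)

DEFAULT_PERCENTILES = (0.10, 0.50, 0.90)


def catalog_hash(catalog: Catalog) -> str:
    """Stable short hash of a catalog's full normalized content."""
    payload = {
        name: (rng.low, rng.mid, rng.high)
        for name, rng in sorted(catalog.parameter_ranges().items())
    }
    payload["__correlations__"] = sorted(catalog.correlations.pairs)
    payload["__constants__"] = (catalog.days_per_month, catalog.learning_hours)
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class SimulationSummary:
    """Distribution summary of one scenario's net benefits (US$/hh-month)."""

    scenario_id: str
    n_draws: int
    seed: int
    percentiles: dict[float, float]
    fraction_positive: float
    component_means: dict[str, float]
    catalog_hash: str = ""
    model_config: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "scenario_id": self.scenario_id,
            "n_draws": self.n_draws,
            "seed": self.seed,
            "percentiles": {f"{p:g}": v for p, v in self.percentiles.items()},
            "fraction_positive": self.fraction_positive,
            "component_means": self.component_means,
            "catalog_hash": self.catalog_hash,
            "model_config": self.model_config,
        }


@dataclass
class SimulationRun:
    """Everything produced by one Monte Carlo experiment."""

    draws: DrawMatrix
    scenarios: list[Scenario]
    summaries: dict[str, SimulationSummary]
    nets: dict[str, np.ndarray]
    breakdowns: dict[str, CostBenefitBreakdown]
    catalog_hash: str
    config: ModelConfig

    def summary(self, scenario: Scenario | str) -> SimulationSummary:
        key = scenario if isinstance(scenario, str) else scenario.scenario_id
        return self.summaries[key]

    def net(self, scenario: Scenario | str) -> np.ndarray:
        key = scenario if isinstance(scenario, str) else scenario.scenario_id
        return self.nets[key]


def _summarize(
    scenario: Scenario,
    breakdown: CostBenefitBreakdown,
    seed: int,
    percentiles,
    cat_hash: str,
    config: ModelConfig,
) -> SimulationSummary:
    net = np.asarray(breakdown.net)
    pct = {
        float(p): float(np.percentile(net, 100.0 * p, method="linear"))
        for p in percentiles
    }
    means = {
        name: float(np.mean(np.asarray(getattr(breakdown, name))))
        for name in BREAKDOWN_COLUMNS
    }
    return SimulationSummary(
        scenario_id=scenario.scenario_id,
        n_draws=net.size,
        seed=seed,
        percentiles=pct,
        fraction_positive=float(np.mean(net > 0)),
        component_means=means,
        catalog_hash=cat_hash,
        model_config=config.as_dict(),
    )


def run(
    catalog: Catalog,
    scenarios: list[Scenario],
    n_draws: int = 10_000,
    seed: int = 0,
    config: ModelConfig = DEFAULT_CONFIG,
    percentiles=DEFAULT_PERCENTILES,
    draws: DrawMatrix | None = None,
) -> SimulationRun:
    """Evaluate every scenario on one shared draw matrix.

    A precomputed ``draws`` matrix may be passed to replay or extend an
    experiment; otherwise ``n_draws`` realizations are drawn with ``seed``.
    """
    if n_draws < 100:
        warnings.warn(
            f"n_draws={n_draws} is small; percentile estimates will be noisy",
            stacklevel=2,
        )
    if draws is None:
        draws = sample(catalog, n_draws, seed)
    mapping = draws.as_mapping()
    cat_hash = catalog_hash(catalog)
    summaries: dict[str, SimulationSummary] = {}
    nets: dict[str, np.ndarray] = {}
    breakdowns: dict[str, CostBenefitBreakdown] = {}
    for scenario in scenarios:
        bd = evaluate(catalog, mapping, scenario, config)
        sid = scenario.scenario_id
        breakdowns[sid] = bd
        nets[sid] = np.asarray(bd.net)
        summaries[sid] = _summarize(
            scenario, bd, draws.seed, percentiles, cat_hash, config
        )
        logger.info(
            "scenario %s: median %.3f, P(net>0)=%.3f",
            sid,
            summaries[sid].percentiles[0.5],
            summaries[sid].fraction_positive,
        )
    return SimulationRun(
        draws=draws,
        scenarios=list(scenarios),
        summaries=summaries,
        nets=nets,
        breakdowns=breakdowns,
        catalog_hash=cat_hash,
        config=config,
    )


def cdf_table(
    sim: SimulationRun, scenario: Scenario | str, probabilities
) -> pd.DataFrame:
    """Tabulate the empirical net-benefit CDF on a probability grid.

    Returns a two-column frame (probability, net US$/hh-month) suitable for
    plotting cumulative-distribution comparisons across stoves; values are
    non-decreasing in probability by construction.
    """
    net = sim.net(scenario)
    probs = np.asarray(sorted(probabilities), dtype=float)
    if probs.size and (probs[0] < 0.0 or probs[-1] > 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    values = np.percentile(net, 100.0 * probs, method="linear")
    return pd.DataFrame({"probability": probs, "net_benefit": values})


def write_summaries(
    sim: SimulationRun, out_dir: str | Path, run_id: str = "run"
) -> list[Path]:
    """Serialize summaries as CSV + JSON with a manifest; returns paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    rows = []
    for sid, summary in sim.summaries.items():
        jpath = out / f"{run_id}_{sid}.json"
        with open(jpath, "w") as fh:
            json.dump(summary.as_dict(), fh, indent=2, sort_keys=True)
        written.append(jpath)
        for p, v in summary.percentiles.items():
            rows.append(
                {
                    "scenario_id": sid,
                    "percentile": p,
                    "net_benefit": v,
                    "fraction_positive": summary.fraction_positive,
                }
            )
    cpath = out / f"{run_id}_summaries.csv"
    pd.DataFrame(rows).to_csv(cpath, index=False)
    written.append(cpath)
    manifest = {
        "run_id": run_id,
        "seed": sim.draws.seed,
        "n_draws": sim.draws.n_draws,
        "catalog_hash": sim.catalog_hash,
        "model_config": sim.config.as_dict(),
        "psd_adjustment": sim.draws.psd_adjustment,
        "scenarios": [s.scenario_id for s in sim.scenarios],
    }
    mpath = out / f"{run_id}_manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    written.append(mpath)
    return written
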