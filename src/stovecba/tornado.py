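"""One-way sensitivity sweeps (tornado-diagram data).

Each uncertain parameter relevant to a scenario is moved to its low and
high bound while every other parameter sits at its central (Mid) value;
the swing |outcome(high) - outcome(low)| ranks the parameters.  Sweeps are
deliberately uncorrelated — the assumed rank correlations belong to the
Monte Carlo analysis, not to one-at-a-time perturbation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .catalog import Catalog, midpoint_draw
from .model import DEFAULT_CONFIG, ModelConfig, Scenario, evaluate

__all__ = ["TornadoEntry", "tornado", "tornado_frame", "relevant_parameters"]


@dataclass(frozen=True)
class TornadoEntry:
    """Outcome span of one parameter's one-way sweep (US$/hh-month)."""

    parameter: str
    outcome_at_low: float
    outcome_at_high: float
    baseline_outcome: float

    @property
    def swing(self) -> float:
        return abs(self.outcome_at_high - self.outcome_at_low)


def relevant_parameters(catalog: Catalog, scenario: Scenario) -> list[str]:
    """Uncertain parameters that can move this scenario's outcome.

    Stove- and fuel-scoped parameters of stoves outside the comparison are
    excluded (they would contribute zero-swing rows); constants are
    excluded as having no range to sweep.
    """
    in_play_stoves = {scenario.baseline_stove, scenario.candidate_stove}
    in_play_fuels = {catalog.stoves[s].fuel_id for s in in_play_stoves}
    names = []
    for name, rng in catalog.parameter_ranges().items():
        if rng.is_degenerate:
            continue
        if "." in name:
            scope = name.split(".")[1] if name.startswith("fuel.") else name.split(".")[0]
            if name.startswith("fuel."):
                if scope not in in_play_fuels:
                    continue
                # the wood price enters every wood-baseline scenario through
                # the purchased fraction of baseline fuel
            elif scope not in in_play_stoves:
                continue
        names.append(name)
    return names


def tornado(
    catalog: Catalog,
    scenario: Scenario,
    config: ModelConfig = DEFAULT_CONFIG,
) -> list[TornadoEntry]:
    """One TornadoEntry per relevant uncertain parameter, sorted by swing."""
    mid = midpoint_draw(catalog)
    baseline = float(evaluate(catalog, mid, scenario, config).net)
    ranges = catalog.parameter_ranges()
    entries = []
    for name in relevant_parameters(catalog, scenario):
        rng = ranges[name]
        outcomes = {}
        for bound in ("low", "high"):
            draw = dict(mid)
            draw[name] = getattr(rng, bound)
            outcomes[bound] = float(evaluate(catalog, draw, scenario, config).net)
        entries.append(
            TornadoEntry(
                parameter=name,
                outcome_at_low=outcomes["low"],
                outcome_at_high=outcomes["high"],
                baseline_outcome=baseline,
            )
        )
    entries.sort(key=lambda e: e.swing, reverse=True)
    return entries


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    """Tornado data as a tidy frame (the CSV contract for reporting)."""
    return pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "low_outcome": [e.outcome_at_low for e in entries],
            "high_outcome": [e.outcome_at_high for e in entries],
            "swing": [e.swing for e in entries],
            "baseline": [e.baseline_outcome for e in entries],
        }
    )


def save_tornado(entries: list[TornadoEntry], path: str | Path) -> None:
    tornado_frame(entries).to_csv(path, index=False)


def plot_tornado(entries: list[TornadoEntry], path: str | Path,
                 top: int = 15) -> None:
    """Horizontal-bar tornado plot (requires matplotlib; CSV is the contract)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    shown = entries[:top][::-1]
    fig, ax = plt.subplots(figsize=(7, 0.35 * len(shown) + 1.5))
    for i, e in enumerate(shown):
        lo, hi = sorted((e.outcome_at_low, e.outcome_at_high))
        ax.barh(i, hi - lo, left=lo, height=0.6, color="#4878a8")
    ax.axvline(shown[0].baseline_outcome if shown else 0.0, color="crimson",
               lw=1.5, label="all-central outcome")
    ax.set_yticks(range(len(shown)))
    ax.set_yticklabels([e.parameter for e in shown], fontsize=8)
    ax.set_xlabel("net benefits (US$/hh-month)")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
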