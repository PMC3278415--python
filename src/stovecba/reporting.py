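"""Reproduction of the headline policy table and scenario bookkeeping.

The headline table summarizes, for each of the seven stove transitions,
the 10th/50th/90th percentiles of monthly household net benefits under
four policy blocks: the private perspective without subsidy; the social
perspective with basic (CO2/CH4/N2O) carbon accounting; the private
perspective with the simulated carbon value transferred to the household
as an offset payment, under basic and under extended (adding CO, NMHC and
black carbon) accounting.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .catalog import Catalog
from .engine import SimulationRun, run
from .model import DEFAULT_CONFIG, ModelConfig, Scenario

__all__ = [
    "SEVEN_TRANSITIONS",
    "TABLE4_BLOCKS",
    "paper_scenarios",
    "table4",
    "format_table4",
    "reference_table4",
]

# the six transitions away from the traditional wood stove, plus the
# charcoal-to-improved-charcoal transition
SEVEN_TRANSITIONS: tuple[tuple[str, str, str], ...] = (
    ("charcoal_traditional", "wood_traditional", "charcoal_traditional"),
    ("wood_ics", "wood_traditional", "wood_ics"),
    ("charcoal_ics", "wood_traditional", "charcoal_ics"),
    ("charcoal_ics_from_charcoal", "charcoal_traditional", "charcoal_ics"),
    ("kerosene", "wood_traditional", "kerosene"),
    ("lpg", "wood_traditional", "lpg"),
    ("electric", "wood_traditional", "electric"),
)

TABLE4_BLOCKS = ("private", "social_basic", "offset_basic", "offset_extended")


def _block_scenario(label: str, baseline: str, candidate: str, block: str) -> Scenario:
    if block == "private":
        return Scenario(baseline, candidate, perspective="private")
    if block == "social_basic":
        return Scenario(baseline, candidate, perspective="social", accounting="basic")
    if block == "offset_basic":
        return Scenario(
            baseline, candidate, perspective="private",
            accounting="basic", carbon_offset_transfer=True,
        )
    if block == "offset_extended":
        return Scenario(
            baseline, candidate, perspective="private",
            accounting="extended", carbon_offset_transfer=True,
        )
    raise ValueError(f"unknown table block {block!r}")


def paper_scenarios(
    blocks=TABLE4_BLOCKS,
    transitions=SEVEN_TRANSITIONS,
) -> list[tuple[str, str, Scenario]]:
    """(row label, block, Scenario) triples for the headline table."""
    out = []
    for label, baseline, candidate in transitions:
        for block in blocks:
            out.append((label, block, _block_scenario(label, baseline, candidate, block)))
    return out


def table4(
    catalog: Catalog,
    n_draws: int = 10_000,
    seed: int = 0,
    config: ModelConfig = DEFAULT_CONFIG,
    blocks=TABLE4_BLOCKS,
    sim: SimulationRun | None = None,
) -> pd.DataFrame:
    """Numeric headline table: one row per (stove transition, policy block).

    All scenario cells are computed from one shared draw matrix so columns
    are directly comparable.  Returns columns (scenario, block, p10, p50,
    p90, fraction_positive).
    """
    triples = paper_scenarios(blocks=blocks)
    if sim is None:
        sim = run(catalog, [s for _, _, s in triples], n_draws=n_draws, seed=seed,
                  config=config)
    rows = []
    for label, block, scenario in triples:
        summary = sim.summary(scenario)
        rows.append(
            {
                "scenario": label,
                "block": block,
                "p10": summary.percentiles[0.10],
                "p50": summary.percentiles[0.50],
                "p90": summary.percentiles[0.90],
                "fraction_positive": summary.fraction_positive,
            }
        )
    return pd.DataFrame(rows)


def _money(x: float) -> str:
    """Render a monetary value, parenthesizing negatives: -1.23 -> ($1.2)."""
    if x < 0:
        return f"(${abs(x):.1f})"
    return f"${x:.1f}"


def format_table4(numeric: pd.DataFrame) -> pd.DataFrame:
    """Wide, printed-style layout: blocks side by side, negatives in parens."""
    blocks = [b for b in TABLE4_BLOCKS if b in set(numeric["block"])]
    out = {}
    for block in blocks:
        sub = numeric[numeric["block"] == block].set_index("scenario")
        for pct, col in (("Low", "p10"), ("Median", "p50"), ("High", "p90")):
            out[f"{block}:{pct}"] = sub[col].map(_money)
    frame = pd.DataFrame(out)
    frame.index.name = "stove_option"
    return frame


def reference_table4() -> pd.DataFrame:
    """The published headline percentiles, as packaged reference data."""
    path = resources.files("stovecba.data") / "table4_reference.csv"
    return pd.read_csv(Path(str(path)))


def compare_table4(numeric: pd.DataFrame) -> pd.DataFrame:
    """Cell-wise comparison of a simulated table against the published one.

    Returns a tidy frame (scenario, block, percentile, simulated, published,
    difference) for every aligned cell; tolerance judgements are left to the
    caller, since agreement varies by block (see the methods note).
    """
    ref = reference_table4().set_index(["scenario", "block"])
    rows = []
    for _, row in numeric.iterrows():
        key = (row["scenario"], row["block"])
        if key not in ref.index:
            continue
        for pct in ("p10", "p50", "p90"):
            rows.append(
                {
                    "scenario": key[0],
                    "block": key[1],
                    "percentile": pct,
                    "simulated": row[pct],
                    "published": ref.loc[key, pct],
                    "difference": row[pct] - ref.loc[key, pct],
                }
            )
    return pd.DataFrame(rows)
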