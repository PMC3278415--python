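"""Deterministic monthly cost-benefit model for a stove transition.

All quantities are per household per month, in US$.  The model compares a
baseline stove (traditional wood-burning, or traditional charcoal-burning
for the charcoal-to-improved-charcoal transition) against a candidate
stove, for one fully resolved parameter draw.  Every function accepts
either scalar draws or NumPy arrays of draws (one entry per Monte Carlo
realization) and is written to broadcast, so the simulation engine can
evaluate ten thousand realizations in a single call.

Cost components (monthly): annualized capital (``cap``), program delivery
(``prog``), net operation & maintenance (``om``), net fuel in money and
time (``fuel_net``), and one-off learning time annualized like capital
(``learn``).  Benefit components: reduced respiratory morbidity (``morb``)
and mortality (``mort``), cooking-time savings (``timesav``), the value of
avoided greenhouse-gas emissions (``carb``) and of avoided fuelwood
harvesting (``bio``).  Net benefits are benefits minus costs; the private
perspective counts only health and time benefits (plus carbon when an
offset payment is passed through), the social perspective adds the
environmental terms and ignores capital subsidies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .catalog import Catalog

__all__ = [
    "Scenario",
    "ModelConfig",
    "CostBenefitBreakdown",
    "capital_recovery_factor",
    "baseline_energy_and_fuel",
    "candidate_fuel_use",
    "net_fuel_cost",
    "fixed_costs",
    "health_benefits",
    "time_savings",
    "environmental_benefits",
    "evaluate",
    "referenced_symbols",
    "BREAKDOWN_COLUMNS",
]

BASELINE_IDS = ("wood_traditional", "charcoal_traditional")
BREAKDOWN_COLUMNS = (
    "cap",
    "prog",
    "om",
    "fuel_net",
    "learn",
    "morb",
    "mort",
    "timesav",
    "carb",
    "bio",
    "net",
)


@dataclass(frozen=True)
class Scenario:
    """One stove transition under one accounting and policy setting."""

    baseline_stove: str
    candidate_stove: str
    perspective: str = "private"          # "private" | "social"
    accounting: str = "basic"             # "basic" | "extended"
    capital_subsidy_fraction: float = 0.0
    carbon_offset_transfer: bool = False

    def __post_init__(self) -> None:
        if self.baseline_stove not in BASELINE_IDS:
            raise ValueError(
                f"baseline must be one of {BASELINE_IDS}, got {self.baseline_stove!r}"
            )
        if self.candidate_stove == self.baseline_stove:
            raise ValueError("candidate stove must differ from the baseline")
        if self.baseline_stove == "charcoal_traditional" and (
            self.candidate_stove != "charcoal_ics"
        ):
            raise ValueError(
                "the charcoal baseline is only compared against charcoal_ics"
            )
        if self.perspective not in ("private", "social"):
            raise ValueError(f"unknown perspective {self.perspective!r}")
        if self.accounting not in ("basic", "extended"):
            raise ValueError(f"unknown accounting variant {self.accounting!r}")
        if not 0.0 <= self.capital_subsidy_fraction <= 1.0:
            raise ValueError("capital_subsidy_fraction must lie in [0, 1]")

    @property
    def scenario_id(self) -> str:
        bits = [self.candidate_stove]
        if self.baseline_stove != "wood_traditional":
            bits.append(f"from_{self.baseline_stove}")
        bits.append(self.perspective)
        bits.append(self.accounting)
        if self.capital_subsidy_fraction:
            bits.append(f"sub{self.capital_subsidy_fraction:g}")
        if self.carbon_offset_transfer:
            bits.append("offset")
        return "_".join(bits)


@dataclass(frozen=True)
class ModelConfig:
    """Documented model switches.

    gamma_basis
        How the per-MJ carbon intensity is applied: ``"fuel"`` charges it
        per MJ of fuel heat released (mass * energy content * intensity);
        ``"useful"`` charges it per MJ of useful cooking energy (the same
        product further scaled by heat-transfer efficiency).  The default
        is ``"fuel"``: the magnitude of the wood intensity (sustainable
        harvest, CO2 recycled into regrowth) is only consistent with a
        per-fuel-heat reading.
    mortality_includes_hhsize
        Whether the per-person mortality-risk reduction is multiplied by
        household size.  Default False: respiratory mortality is
        concentrated in the at-risk minority of the household (young
        children for ALRI, the primary cook for COPD), not spread over
        every member.
    mortality_risk_multiplier
        Size of that at-risk pool, in persons (or a per-member weight when
        ``mortality_includes_hhsize`` is True).  Default 0.15, calibrated
        once against the published one-way sensitivity endpoints; see the
        methods note.
    """

    gamma_basis: str = "fuel"
    mortality_includes_hhsize: bool = False
    mortality_risk_multiplier: float = 0.15

    def __post_init__(self) -> None:
        if self.gamma_basis not in ("fuel", "useful"):
            raise ValueError(f"unknown gamma basis {self.gamma_basis!r}")

    def as_dict(self) -> dict:
        return {
            "gamma_basis": self.gamma_basis,
            "mortality_includes_hhsize": self.mortality_includes_hhsize,
            "mortality_risk_multiplier": self.mortality_risk_multiplier,
        }


DEFAULT_CONFIG = ModelConfig()


@dataclass
class CostBenefitBreakdown:
    """Monthly cost/benefit components (US$/hh-month) for one scenario.

    ``net`` is benefits minus costs under the scenario's perspective rules;
    each field is a scalar or an array over draws.
    """

    cap: np.ndarray | float
    prog: np.ndarray | float
    om: np.ndarray | float
    fuel_net: np.ndarray | float
    learn: np.ndarray | float
    morb: np.ndarray | float
    mort: np.ndarray | float
    timesav: np.ndarray | float
    carb: np.ndarray | float
    bio: np.ndarray | float
    net: np.ndarray | float

    def as_record(self) -> dict[str, np.ndarray | float]:
        return {name: getattr(self, name) for name in BREAKDOWN_COLUMNS}


class _View:
    """Thin accessor over a draw mapping for one catalog."""

    def __init__(self, catalog: Catalog, draw: Mapping):
        self.cat = catalog
        self.d = draw

    def g(self, name: str):
        return self.d[name]

    def s(self, stove_id: str, fld: str):
        return self.d[f"{stove_id}.{fld}"]

    def f(self, fuel_id: str, fld: str):
        return self.d[f"fuel.{fuel_id}.{fld}"]

    def fuel_of(self, stove_id: str) -> str:
        return self.cat.stoves[stove_id].fuel_id


def capital_recovery_factor(rate, lifespan):
    """Constant annual payment that repays a unit loan over ``lifespan`` years.

    crf = d(1+d)^T / ((1+d)^T - 1); the zero-rate limit is straight-line
    amortization 1/T.
    """
    rate = np.asarray(rate, dtype=float)
    lifespan = np.asarray(lifespan, dtype=float)
    if np.any(lifespan <= 0):
        raise ValueError("stove lifespan must be positive")
    if np.any(rate < 0):
        raise ValueError("discount rate must be non-negative")
    growth = (1.0 + rate) ** lifespan
    with np.errstate(divide="ignore", invalid="ignore"):
        crf = np.where(rate > 0, rate * growth / (growth - 1.0), 1.0 / lifespan)
    return crf if crf.ndim else float(crf)


def baseline_energy_and_fuel(catalog: Catalog, draw: Mapping, scenario: Scenario):
    """Monthly baseline fuel mass (kg) and useful cooking energy (MJ).

    The wood baseline is primitive: mass follows from cooking hours and the
    wood burn rate.  The charcoal baseline is derived by useful-energy
    equivalence — the household needs the same useful cooking energy as its
    wood-burning counterpart, delivered through the traditional charcoal
    stove's efficiency.
    """
    v = _View(catalog, draw)
    days = catalog.days_per_month
    wood_kg = v.g("baseline_cooking_time") * v.g("baseline_fuel_rate") * days
    eff0 = v.s("wood_traditional", "heat_efficiency")
    if np.any(np.asarray(eff0) <= 0):
        raise ValueError("baseline heat efficiency must be positive")
    useful = wood_kg * v.f("wood", "energy_content") * eff0
    if scenario.baseline_stove == "wood_traditional":
        return wood_kg, useful
    eff_c = v.s("charcoal_traditional", "heat_efficiency")
    if np.any(np.asarray(eff_c) <= 0):
        raise ValueError("baseline heat efficiency must be positive")
    charcoal_kg = useful / (v.f("charcoal", "energy_content") * eff_c)
    return charcoal_kg, useful


def candidate_fuel_use(catalog: Catalog, draw: Mapping, scenario: Scenario):
    """Monthly candidate fuel quantity: kg, or kW-hr for the electric stove."""
    v = _View(catalog, draw)
    sid = scenario.candidate_stove
    if catalog.stoves[sid].is_electric:
        # heat_efficiency holds kW-hr drawn per hour of cooking
        return (
            v.g("baseline_cooking_time")
            * v.s(sid, "time_efficiency")
            * catalog.days_per_month
            * v.s(sid, "heat_efficiency")
        )
    _, useful = baseline_energy_and_fuel(catalog, draw, scenario)
    fid = v.fuel_of(sid)
    return useful / (v.f(fid, "energy_content") * v.s(sid, "heat_efficiency"))


def _monthly_fuel_cost(v: _View, catalog, draw, scenario, stove_id, fuel_qty,
                       baseline_qty):
    """Money plus time cost of one stove's monthly fuel."""
    days = catalog.days_per_month
    time_price = v.g("time_value") * v.g("wage")
    fid = v.fuel_of(stove_id)
    if stove_id == "wood_traditional":
        return (
            v.g("wood_purchased_fraction") * v.f("wood", "price") * fuel_qty
            + v.g("collection_time") * days * time_price
        )
    if stove_id == "wood_ics":
        # collection effort scales with the wood mass actually needed
        return (
            v.g("wood_purchased_fraction") * v.f("wood", "price") * fuel_qty
            + v.g("collection_time") * (fuel_qty / baseline_qty) * days * time_price
            + v.g("prep_time") * days * time_price
        )
    # other fuels are purchased ready to burn
    return v.f(fid, "price") * fuel_qty


def net_fuel_cost(catalog: Catalog, draw: Mapping, scenario: Scenario):
    """Monthly net fuel cost of the switch (negative = savings), use-weighted."""
    v = _View(catalog, draw)
    base_qty, _ = baseline_energy_and_fuel(catalog, draw, scenario)
    cand_qty = candidate_fuel_use(catalog, draw, scenario)
    wood_base_qty = base_qty if scenario.baseline_stove == "wood_traditional" else None
    cost0 = _monthly_fuel_cost(
        v, catalog, draw, scenario, scenario.baseline_stove, base_qty, wood_base_qty
    )
    cost_i = _monthly_fuel_cost(
        v, catalog, draw, scenario, scenario.candidate_stove, cand_qty, wood_base_qty
    )
    return v.g("sustained_use") * (cost_i - cost0)


def _discount_rate(v: _View, scenario: Scenario):
    name = (
        "discount_rate_private"
        if scenario.perspective == "private"
        else "discount_rate_social"
    )
    return v.g(name)


def fixed_costs(catalog: Catalog, draw: Mapping, scenario: Scenario,
                config: ModelConfig = DEFAULT_CONFIG):
    """Monthly (cap, prog, om, learn).

    Capital is annualized with the capital recovery factor at the
    perspective's discount rate; the baseline stove's capital is sunk.
    Capital subsidies reduce the household's cost under the private
    perspective only — society still pays full cost.
    """
    v = _View(catalog, draw)
    sid = scenario.candidate_stove
    delta = _discount_rate(v, scenario)
    crf = capital_recovery_factor(delta, v.s(sid, "lifespan"))
    cap = v.s(sid, "capital_cost") * crf / 12.0
    if scenario.perspective == "private":
        cap = cap * (1.0 - scenario.capital_subsidy_fraction)
    prog = v.g("program_cost") / 12.0
    om = (
        v.g("sustained_use")
        * (v.s(sid, "maintenance_cost") - v.s(scenario.baseline_stove, "maintenance_cost"))
        / 12.0
    )
    learn = (
        catalog.learning_hours * v.g("time_value") * v.g("wage") * crf / 12.0
    )
    return cap, prog, om, learn


def health_benefits(catalog: Catalog, draw: Mapping, scenario: Scenario,
                    config: ModelConfig = DEFAULT_CONFIG):
    """Monthly (morb, mort) from reduced ARI incidence and COPD prevalence.

    Effectiveness enters as the candidate-minus-baseline difference, so the
    charcoal-to-improved-charcoal transition is credited only with the
    incremental reduction.  COPD benefits are discounted by the onset delay.
    Morbidity scales with household size; mortality scales with the at-risk
    pool set by the model configuration (see :class:`ModelConfig`).
    """
    v = _View(catalog, draw)
    sid, bid = scenario.candidate_stove, scenario.baseline_stove
    chi = v.g("sustained_use")
    delta = _discount_rate(v, scenario)
    onset = (1.0 + delta) ** v.g("copd_onset_delay")
    eta_ari = v.s(sid, "ari_effectiveness") - v.s(bid, "ari_effectiveness")
    eta_copd = v.s(sid, "copd_effectiveness") - v.s(bid, "copd_effectiveness")
    morb = (
        chi
        * v.g("household_size")
        * (
            v.g("ari_incidence") * eta_ari * v.g("coi_ari")
            + v.g("copd_prevalence") * eta_copd * v.g("coi_copd") / onset
        )
        / 12.0
    )
    pool = config.mortality_risk_multiplier
    if config.mortality_includes_hhsize:
        pool = pool * v.g("household_size")
    mort = (
        chi
        * pool
        * v.g("vsl")
        * (
            v.g("ari_incidence")
            * v.g("alri_fraction")
            * v.g("alri_cfr")
            * eta_ari
            + v.g("copd_death_rate") * eta_copd / onset
        )
        / 12.0
    )
    return morb, mort


def time_savings(catalog: Catalog, draw: Mapping, scenario: Scenario):
    """Monthly value of cooking-time saved (negative if the stove is slower)."""
    v = _View(catalog, draw)
    rel = v.s(scenario.baseline_stove, "time_efficiency") - v.s(
        scenario.candidate_stove, "time_efficiency"
    )
    return (
        v.g("sustained_use")
        * v.g("baseline_cooking_time")
        * rel
        * catalog.days_per_month
        * v.g("time_value")
        * v.g("wage")
    )


def _gamma(v: _View, scenario: Scenario, fuel_id: str):
    # the electric intensity is a single sampled parameter used by both
    # accounting variants (grid emissions are unaffected by stove chemistry)
    if fuel_id == "electricity" or scenario.accounting == "basic":
        return v.f(fuel_id, "carbon_intensity_basic")
    return v.f(fuel_id, "carbon_intensity_extended")


def _emissions(v: _View, catalog, draw, scenario, stove_id, fuel_qty,
               config: ModelConfig):
    """Monthly g CO2-eq from one stove's fuel use."""
    stove = catalog.stoves[stove_id]
    fid = stove.fuel_id
    gamma = _gamma(v, scenario, fid)
    if stove.is_electric:
        return fuel_qty * gamma
    heat = fuel_qty * v.f(fid, "energy_content")
    if config.gamma_basis == "useful":
        heat = heat * v.s(stove_id, "heat_efficiency")
    return heat * gamma


def environmental_benefits(catalog: Catalog, draw: Mapping, scenario: Scenario,
                           config: ModelConfig = DEFAULT_CONFIG):
    """Monthly (carb, bio): avoided emissions value and avoided wood harvest."""
    v = _View(catalog, draw)
    chi = v.g("sustained_use")
    base_qty, _ = baseline_energy_and_fuel(catalog, draw, scenario)
    cand_qty = candidate_fuel_use(catalog, draw, scenario)
    e0 = _emissions(v, catalog, draw, scenario, scenario.baseline_stove, base_qty, config)
    e1 = _emissions(v, catalog, draw, scenario, scenario.candidate_stove, cand_qty, config)
    carb = v.g("carbon_price") * chi * (e0 - e1) / 1e6
    wood0 = base_qty if v.fuel_of(scenario.baseline_stove) == "wood" else 0.0
    wood1 = cand_qty if v.fuel_of(scenario.candidate_stove) == "wood" else 0.0
    bio = v.g("tree_replacement_cost") * chi * (wood0 - wood1)
    return carb, bio


def evaluate(catalog: Catalog, draw: Mapping, scenario: Scenario,
             config: ModelConfig = DEFAULT_CONFIG) -> CostBenefitBreakdown:
    """Full monthly cost-benefit breakdown for one draw and scenario."""
    cap, prog, om, learn = fixed_costs(catalog, draw, scenario, config)
    fuel = net_fuel_cost(catalog, draw, scenario)
    morb, mort = health_benefits(catalog, draw, scenario, config)
    timesav = time_savings(catalog, draw, scenario)
    carb, bio = environmental_benefits(catalog, draw, scenario, config)
    benefits = morb + mort + timesav
    if scenario.perspective == "social":
        benefits = benefits + carb + bio
    elif scenario.carbon_offset_transfer:
        benefits = benefits + carb
    net = benefits - (cap + prog + om + fuel + learn)
    return CostBenefitBreakdown(
        cap=cap, prog=prog, om=om, fuel_net=fuel, learn=learn,
        morb=morb, mort=mort, timesav=timesav, carb=carb, bio=bio, net=net,
    )


class _RecordingDraw(dict):
    """Draw mapping that records which symbols are actually read."""

    def __init__(self, base: Mapping):
        super().__init__(base)
        self.accessed: set[str] = set()

    def __getitem__(self, key):
        self.accessed.add(key)
        return super().__getitem__(key)


def referenced_symbols(catalog: Catalog) -> set[str]:
    """Symbols the model reads, traced over every scenario and switch.

    Used by the symbol-closure test: apart from the documented sunk
    baseline-capital fields, this must equal the catalog's declared
    parameter set — the model reads no undeclared symbol and no declared
    symbol is silently ignored.
    """
    from .catalog import midpoint_draw

    rec = _RecordingDraw(midpoint_draw(catalog))
    candidates = [s for s in catalog.stoves if s != "wood_traditional"]
    for cand in candidates:
        base = "charcoal_traditional" if cand == "charcoal_ics" else "wood_traditional"
        pairs = [(base, cand)]
        if cand == "charcoal_ics":
            pairs.append(("wood_traditional", cand))
        for bid, sid in pairs:
            for persp in ("private", "social"):
                for acct in ("basic", "extended"):
                    for basis in ("fuel", "useful"):
                        evaluate(
                            catalog,
                            rec,
                            Scenario(bid, sid, perspective=persp, accounting=acct),
                            ModelConfig(gamma_basis=basis),
                        )
    return rec.accessed
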