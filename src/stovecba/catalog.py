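"""Parameter catalog: uncertain ranges, stove/fuel blocks, and correlations.

The catalog is the single home of every symbol used by the cost-benefit
model.  It is loaded from a YAML (or JSON) file whose numeric cells mirror
the published literature review verbatim; units are normalized at load time
(percentages to fractions, deaths per 10,000 to probabilities) so that the
model itself works exclusively in fractions, US$, hours, kg and years.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "ParameterRange",
    "FuelSpec",
    "StoveSpec",
    "GlobalParameters",
    "CorrelationSpec",
    "Catalog",
    "CatalogError",
    "SchemaError",
    "ValidationError",
    "load_catalog",
    "save_catalog",
    "midpoint_draw",
    "packaged_catalog_path",
    "packaged_correlations_path",
]

STOVE_IDS = (
    "wood_traditional",
    "wood_ics",
    "charcoal_traditional",
    "charcoal_ics",
    "kerosene",
    "lpg",
    "electric",
)
FUEL_IDS = ("wood", "charcoal", "kerosene", "propane", "electricity")

GLOBAL_FIELDS = (
    "discount_rate_social",
    "discount_rate_private",
    "program_cost",
    "sustained_use",
    "baseline_cooking_time",
    "baseline_fuel_rate",
    "collection_time",
    "prep_time",
    "wood_purchased_fraction",
    "household_size",
    "ari_incidence",
    "copd_prevalence",
    "coi_ari",
    "coi_copd",
    "copd_onset_delay",
    "vsl",
    "alri_fraction",
    "alri_cfr",
    "copd_death_rate",
    "time_value",
    "wage",
    "carbon_price",
    "tree_replacement_cost",
)

STOVE_FIELDS = (
    "capital_cost",
    "lifespan",
    "time_efficiency",
    "heat_efficiency",
    "maintenance_cost",
    "ari_effectiveness",
    "copd_effectiveness",
)

FUEL_FIELDS = (
    "price",
    "energy_content",
    "carbon_intensity_basic",
    "carbon_intensity_extended",
)

# parameters that must stay within [0, 1.5] after unit normalization
# (time efficiency may exceed 1: an "improved" stove can cook slower)
_FRACTION_GLOBALS = frozenset(
    {
        "discount_rate_social",
        "discount_rate_private",
        "sustained_use",
        "wood_purchased_fraction",
        "copd_prevalence",
        "alri_fraction",
        "alri_cfr",
        "time_value",
    }
)
_FRACTION_STOVE_FIELDS = frozenset(
    {"time_efficiency", "ari_effectiveness", "copd_effectiveness"}
)


class CatalogError(Exception):
    """Base class for catalog problems."""


class SchemaError(CatalogError):
    """The file does not follow the documented catalog schema."""


class ValidationError(CatalogError):
    """The file parses but violates a model invariant."""


@dataclass(frozen=True)
class ParameterRange:
    """One uncertain scalar with its plausible low/mid/high values.

    ``mid`` is the central literature value, which need not be the midpoint
    of ``[low, high]`` (stove costs, for instance, are strongly skewed).
    """

    name: str
    low: float
    mid: float
    high: float
    units: str = ""

    def __post_init__(self) -> None:
        if not (self.low <= self.mid <= self.high):
            raise ValidationError(
                f"parameter {self.name!r}: requires low <= mid <= high, "
                f"got ({self.low}, {self.mid}, {self.high})"
            )

    @property
    def is_degenerate(self) -> bool:
        return self.low == self.high

    def as_dict(self) -> dict:
        if self.is_degenerate and self.low == self.mid:
            return {"value": self.low, "units": self.units}
        return {
            "low": self.low,
            "mid": self.mid,
            "high": self.high,
            "units": self.units,
        }


def _normalize(name: str, raw: Mapping, *, fraction_cap: bool) -> ParameterRange:
    """Build a ParameterRange from a schema node, converting printed units."""
    if not isinstance(raw, Mapping):
        raise SchemaError(f"parameter {name!r}: expected a mapping, got {raw!r}")
    units = str(raw.get("units", ""))
    if "value" in raw:
        lo = mid = hi = float(raw["value"])
    else:
        try:
            lo, mid, hi = (float(raw[k]) for k in ("low", "mid", "high"))
        except KeyError as exc:
            raise SchemaError(f"parameter {name!r}: missing field {exc}") from exc
    scale = 1.0
    if units.startswith("percent"):
        scale = 1e-2
        units = units.replace("percent", "fraction", 1)
    elif units.startswith("deaths/10000"):
        scale = 1e-4
        units = units.replace("deaths/10000", "deaths/person", 1)
    rng = ParameterRange(name, lo * scale, mid * scale, hi * scale, units)
    if fraction_cap and not (0.0 <= rng.low and rng.high <= 1.5):
        raise ValidationError(
            f"parameter {name!r}: fraction-valued range must lie in [0, 1.5], "
            f"got ({rng.low}, {rng.high})"
        )
    return rng


@dataclass(frozen=True)
class FuelSpec:
    """Physical and market properties of one cooking fuel."""

    fuel_id: str
    price: ParameterRange            # US$/kg (US$/kW-hr for electricity)
    energy_content: ParameterRange   # MJ/kg (MJ/kW-hr for electricity)
    carbon_intensity_basic: ParameterRange     # g CO2-eq/MJ (g/kW-hr for electricity)
    carbon_intensity_extended: ParameterRange  # adds CO, NMHC, black carbon


@dataclass(frozen=True)
class StoveSpec:
    """Per-stove parameter block.

    For the electric stove ``heat_efficiency`` is electricity drawn per hour
    of cooking (kW-hr/hr) rather than a heat-transfer ratio; ``is_electric``
    flags that consumption is computed per cooking-hour.
    """

    stove_id: str
    fuel_id: str
    capital_cost: ParameterRange
    lifespan: ParameterRange
    time_efficiency: ParameterRange
    heat_efficiency: ParameterRange
    maintenance_cost: ParameterRange
    ari_effectiveness: ParameterRange
    copd_effectiveness: ParameterRange

    @property
    def is_electric(self) -> bool:
        return self.fuel_id == "electricity"


@dataclass(frozen=True)
class GlobalParameters:
    """Household, economic and health parameters shared across stoves."""

    ranges: Mapping[str, ParameterRange]

    def __getattr__(self, name: str) -> ParameterRange:
        try:
            return self.ranges[name]
        except KeyError:
            raise AttributeError(name) from None

    def __iter__(self):
        return iter(self.ranges.items())


@dataclass(frozen=True)
class CorrelationSpec:
    """Pairwise rank correlations, listed once per unordered pair.

    Names prefixed ``stove:`` are templates expanded stove-by-stove (the
    correlation couples each stove's own parameters); concrete names refer
    to global or fuel-level columns.
    """

    pairs: tuple[tuple[str, str, float], ...] = ()

    def __post_init__(self) -> None:
        for a, b, r in self.pairs:
            if not (-1.0 <= r <= 1.0):
                raise ValidationError(
                    f"correlation ({a}, {b}): {r} outside [-1, 1]"
                )
            if a == b:
                raise ValidationError(f"correlation pairs a parameter with itself: {a}")

    def expand(self, catalog: "Catalog") -> list[tuple[str, str, float]]:
        """Resolve stove-scoped templates against the catalog's columns."""
        known = set(catalog.parameter_ranges())
        out: list[tuple[str, str, float]] = []
        for a, b, r in self.pairs:
            if a.startswith("stove:") or b.startswith("stove:"):
                for sid in catalog.stoves:
                    ca = f"{sid}.{a[6:]}" if a.startswith("stove:") else a
                    cb = f"{sid}.{b[6:]}" if b.startswith("stove:") else b
                    out.append((ca, cb, r))
            else:
                out.append((a, b, r))
        for ca, cb, _ in out:
            if ca not in known or cb not in known:
                missing = ca if ca not in known else cb
                raise ValidationError(f"correlation names unknown parameter {missing!r}")
        return out


@dataclass(frozen=True)
class Catalog:
    """A fully validated model parameterization."""

    globals_: GlobalParameters
    stoves: Mapping[str, StoveSpec]
    fuels: Mapping[str, FuelSpec]
    correlations: CorrelationSpec = field(default_factory=CorrelationSpec)
    days_per_month: float = 30.0
    learning_hours: float = 0.0

    def parameter_ranges(self) -> dict[str, ParameterRange]:
        """Every model symbol, keyed by its draw-matrix column name."""
        cols: dict[str, ParameterRange] = {}
        for name, rng in self.globals_:
            cols[name] = rng
        for sid, stove in self.stoves.items():
            for f in STOVE_FIELDS:
                cols[f"{sid}.{f}"] = getattr(stove, f)
        for fid, fuel in self.fuels.items():
            for f in FUEL_FIELDS:
                cols[f"fuel.{fid}.{f}"] = getattr(fuel, f)
        return cols

    def validate(self) -> None:
        for fid in ("wood", "charcoal"):
            fuel = self.fuels[fid]
            if fuel.carbon_intensity_extended.mid < fuel.carbon_intensity_basic.mid:
                raise ValidationError(
                    f"fuel {fid!r}: extended carbon intensity below basic"
                )
        for sid, stove in self.stoves.items():
            if stove.fuel_id not in self.fuels:
                raise SchemaError(f"stove {sid!r}: unknown fuel {stove.fuel_id!r}")


def packaged_catalog_path() -> Path:
    return Path(str(resources.files("stovecba.data") / "table2_catalog.yaml"))


def packaged_correlations_path() -> Path:
    return Path(str(resources.files("stovecba.data") / "table3_correlations.yaml"))


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, Mapping) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def _build(doc: Mapping) -> Catalog:
    for key in ("globals", "stoves", "fuels"):
        if key not in doc:
            raise SchemaError(f"catalog missing top-level section {key!r}")
    gl = {}
    for name in GLOBAL_FIELDS:
        if name not in doc["globals"]:
            raise SchemaError(f"globals missing parameter {name!r}")
        gl[name] = _normalize(
            name, doc["globals"][name], fraction_cap=name in _FRACTION_GLOBALS
        )
    fuels = {}
    for fid in FUEL_IDS:
        if fid not in doc["fuels"]:
            raise SchemaError(f"missing fuel block {fid!r}")
        node = doc["fuels"][fid]
        fuels[fid] = FuelSpec(
            fid,
            *(
                _normalize(f"fuel.{fid}.{f}", node[f], fraction_cap=False)
                for f in FUEL_FIELDS
            ),
        )
    stoves = {}
    for sid in STOVE_IDS:
        if sid not in doc["stoves"]:
            raise SchemaError(f"missing stove block {sid!r}")
        node = doc["stoves"][sid]
        kwargs = {}
        for f in STOVE_FIELDS:
            if f not in node:
                raise SchemaError(f"stove {sid!r}: missing field {f!r}")
            cap = f in _FRACTION_STOVE_FIELDS or (
                f == "heat_efficiency" and node.get("fuel") != "electricity"
            )
            kwargs[f] = _normalize(f"{sid}.{f}", node[f], fraction_cap=cap)
        stoves[sid] = StoveSpec(sid, node.get("fuel", ""), **kwargs)
    pairs = tuple(
        (str(a), str(b), float(r))
        for a, b, r in (doc.get("correlations") or {}).get("pairs", [])
    )
    constants = doc.get("constants") or {}
    cat = Catalog(
        GlobalParameters(gl),
        stoves,
        fuels,
        CorrelationSpec(pairs),
        days_per_month=float(constants.get("days_per_month", 30.0)),
        learning_hours=float(constants.get("learning_hours", 0.0)),
    )
    cat.validate()
    cat.correlations.expand(cat)  # verifies every named parameter exists
    return cat


def load_catalog(
    path: str | Path | None = None,
    correlations_path: str | Path | None = None,
    *,
    use_defaults: bool = True,
) -> Catalog:
    """Load and validate a catalog file.

    Omitted fields are filled from the packaged default catalog unless
    ``use_defaults`` is False.  With no arguments the packaged defaults
    (parameter ranges plus the assumed correlations) are returned.
    JSON files are accepted anywhere YAML is.
    """
    with open(packaged_catalog_path()) as fh:
        doc = yaml.safe_load(fh) if use_defaults else {}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, Mapping):
            raise SchemaError(f"{path}: catalog file must be a mapping")
        doc = _deep_merge(doc or {}, user)
    if correlations_path is None and "correlations" not in doc:
        correlations_path = packaged_correlations_path()
    if correlations_path is not None:
        with open(correlations_path) as fh:
            cdoc = yaml.safe_load(fh) or {}
        doc["correlations"] = cdoc if "pairs" in cdoc else {"pairs": []}
    return _build(doc)


def save_catalog(catalog: Catalog, path: str | Path) -> None:
    """Write a catalog back to YAML (normalized units)."""
    doc: dict = {
        "constants": {
            "days_per_month": catalog.days_per_month,
            "learning_hours": catalog.learning_hours,
        },
        "globals": {n: r.as_dict() for n, r in catalog.globals_},
        "fuels": {
            fid: {f: getattr(fuel, f).as_dict() for f in FUEL_FIELDS}
            for fid, fuel in catalog.fuels.items()
        },
        "stoves": {
            sid: {
                "fuel": stove.fuel_id,
                **{f: getattr(stove, f).as_dict() for f in STOVE_FIELDS},
            }
            for sid, stove in catalog.stoves.items()
        },
        "correlations": {"pairs": [list(p) for p in catalog.correlations.pairs]},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def midpoint_draw(catalog: Catalog) -> dict[str, float]:
    """Resolve every parameter to its central (Mid column) value.

    This is the deterministic reference evaluation used by the tornado
    analysis, not the mean of each range.
    """
    return {name: rng.mid for name, rng in catalog.parameter_ranges().items()}
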