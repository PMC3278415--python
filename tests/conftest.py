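import dataclasses

import pytest

from stovecba import load_catalog, midpoint_draw, sample
from stovecba.catalog import (
    Catalog,
    CorrelationSpec,
    FuelSpec,
    GlobalParameters,
    ParameterRange,
    STOVE_FIELDS,
    FUEL_FIELDS,
    StoveSpec,
)


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def mid(catalog):
    return midpoint_draw(catalog)


@pytest.fixture(scope="session")
def draws10k(catalog):
    return sample(catalog, 10_000, 123)


def collapse_catalog(catalog: Catalog) -> Catalog:
    """Degenerate copy: every range pinned to its mid (a deterministic world)."""

    def c(r: ParameterRange) -> ParameterRange:
        return ParameterRange(r.name, r.mid, r.mid, r.mid, r.units)

    stoves = {
        sid: StoveSpec(sid, s.fuel_id, *(c(getattr(s, f)) for f in STOVE_FIELDS))
        for sid, s in catalog.stoves.items()
    }
    fuels = {
        fid: FuelSpec(fid, *(c(getattr(fu, f)) for f in FUEL_FIELDS))
        for fid, fu in catalog.fuels.items()
    }
    globals_ = GlobalParameters({n: c(r) for n, r in catalog.globals_})
    return dataclasses.replace(
        catalog, globals_=globals_, stoves=stoves, fuels=fuels
    )


@pytest.fixture(scope="session")
def degenerate_catalog(catalog):
    return collapse_catalog(catalog)
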