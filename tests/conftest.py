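import datetime as dt

import pytest

from habledger import (
    GuildWeightTable,
    Parcel,
    ServiceAreaLedger,
    default_ecotypes,
    make_toronto_fixture,
)

BASE_DATE = dt.date(2024, 1, 1)


@pytest.fixture
def toronto():
    """Packaged worked example at class suitabilities, journal included."""
    return make_toronto_fixture()


@pytest.fixture
def toronto_baseline():
    """Worked example baseline only (no journal), class suitabilities."""
    return make_toronto_fixture(with_journal=False)


@pytest.fixture
def toronto_unit():
    """Worked example at unit suitability: the supply-sheet variant."""
    return make_toronto_fixture(unit_suitability=True)


def small_ledger(parcels=None, schedule="step", maturation_days=365):
    """A minimal service area with the default ecotype/weight tables."""
    parcels = parcels if parcels is not None else []
    return ServiceAreaLedger(
        name="test-area",
        ecotypes=default_ecotypes(),
        guild_weights=GuildWeightTable(),
        parcels={p.parcel_id: p for p in parcels},
        maturation_schedule=schedule,
        maturation_days=maturation_days,
    )


@pytest.fixture
def land_and_bay():
    """1 ha of convertible land plus 1 ha of moderate embayment habitat."""
    return small_ledger(
        [
            Parcel("land-1", "terrestrial", 1.0, 0.0, terrestrial_class="mainland"),
            Parcel("bay-1", "embayment", 1.0, 0.5),
        ]
    )
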