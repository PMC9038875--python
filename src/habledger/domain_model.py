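"""Domain types for aquatic habitat-banking ledgers.

The accounting unit throughout is the productivity-weighted suitable area
(PWSA): hectares, weighted first by within-ecotype habitat suitability
(giving weighted suitable area, WSA) and then by the ecotype's potential
productivity index (PPI), the between-ecotype exchange rate.  A service
area (integrated planning area) holds an ecotype table, an optional
thermal-guild x life-stage weight matrix, a parcel inventory, notional
objectives, and an append-only transaction journal.

Types here are deliberately permissive containers: invalid states are
representable and :func:`validate_ledger` reports them as violations
instead of raising, so that inventories read from files can be inspected
before being trusted.
"""

from __future__ import annotations

import copy
import datetime as _dt
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

AQUATIC_ECOTYPES: tuple[str, ...] = (
    "rivermouth",
    "wetland",
    "embayment",
    "open_coast",
    "offshore",
)
#: Terrestrial land inside the planning boundary is carried as a sixth
#: ecotype with PPI 0 so that land<->water conversions are ordinary
#: ecotype changes and total area is conserved.
ECOTYPES: tuple[str, ...] = AQUATIC_ECOTYPES + ("terrestrial",)

THERMAL_GUILDS: tuple[str, ...] = ("cold", "cool", "warm")
LIFE_STAGES: tuple[str, ...] = ("spawning", "nursery", "juv_ad")

PARCEL_STATUSES: tuple[str, ...] = ("tradable", "reserve", "retired")

TRANSACTION_KINDS: tuple[str, ...] = (
    "deposit",
    "withdrawal",
    "trade",
    "transfer_out",
    "transfer_in",
    "reservation",
)

#: Default potential productivity indices per ecotype (dimensionless,
#: relative maximum ongoing productivity; terrestrial carries zero
#: aquatic value).
DEFAULT_PPI: dict[str, float] = {
    "rivermouth": 1.5,
    "wetland": 2.0,
    "embayment": 1.0,
    "open_coast": 0.5,
    "offshore": 0.25,
    "terrestrial": 0.0,
}

#: Default percent weights over (thermal guild, life stage) per aquatic
#: ecotype.  Each ecotype column sums to 100: coldwater guilds weigh most
#: on the open coast and offshore, warmwater guilds in rivermouths,
#: wetlands and embayments, the coolwater guild sits in between.
DEFAULT_GUILD_WEIGHTS: dict[str, dict[tuple[str, str], float]] = {
    "rivermouth": {
        ("cold", "spawning"): 6, ("cold", "nursery"): 7, ("cold", "juv_ad"): 8,
        ("cool", "spawning"): 11, ("cool", "nursery"): 11, ("cool", "juv_ad"): 11,
        ("warm", "spawning"): 15, ("warm", "nursery"): 16, ("warm", "juv_ad"): 15,
    },
    "wetland": {
        ("cold", "spawning"): 4, ("cold", "nursery"): 4, ("cold", "juv_ad"): 2,
        ("cool", "spawning"): 11, ("cool", "nursery"): 10, ("cool", "juv_ad"): 9,
        ("warm", "spawning"): 19, ("warm", "nursery"): 22, ("warm", "juv_ad"): 19,
    },
    "embayment": {
        ("cold", "spawning"): 7, ("cold", "nursery"): 6, ("cold", "juv_ad"): 5,
        ("cool", "spawning"): 15, ("cool", "nursery"): 17, ("cool", "juv_ad"): 17,
        ("warm", "spawning"): 11, ("warm", "nursery"): 11, ("warm", "juv_ad"): 11,
    },
    "open_coast": {
        ("cold", "spawning"): 22, ("cold", "nursery"): 20, ("cold", "juv_ad"): 18,
        ("cool", "spawning"): 8, ("cool", "nursery"): 12, ("cool", "juv_ad"): 10,
        ("warm", "spawning"): 2, ("warm", "nursery"): 4, ("warm", "juv_ad"): 4,
    },
    "offshore": {
        ("cold", "spawning"): 20, ("cold", "nursery"): 22, ("cold", "juv_ad"): 24,
        ("cool", "spawning"): 8, ("cool", "nursery"): 12, ("cool", "juv_ad"): 10,
        ("warm", "spawning"): 1, ("warm", "nursery"): 1, ("warm", "juv_ad"): 2,
    },
}

#: Representative mean suitabilities of the three reporting quality classes.
QUALITY_CLASS_VALUES: dict[str, float] = {"High": 0.75, "Med": 0.50, "Low": 0.25}

Suitability = Union[float, Mapping[tuple[str, str], float]]


@dataclass(frozen=True)
class EcotypeSpec:
    """An ecotype label with its potential productivity index (PPI)."""

    name: str
    ppi: float
    description: str = ""


@dataclass(frozen=True)
class QualityClass:
    """A High/Med/Low reporting band with its representative suitability."""

    label: str
    representative_suitability: float


HIGH = QualityClass("High", 0.75)
MED = QualityClass("Med", 0.50)
LOW = QualityClass("Low", 0.25)


@dataclass
class GuildWeightTable:
    """Percent weights over (thermal guild, life stage) per ecotype.

    ``weights[ecotype][(guild, stage)]`` is a percentage; a valid column
    is non-negative and sums to 100, so the normalised weights form a
    convex combination over the nine guild-stage cells.
    """

    weights: dict[str, dict[tuple[str, str], float]] = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_GUILD_WEIGHTS)
    )

    def column(self, ecotype: str) -> dict[tuple[str, str], float]:
        return self.weights[ecotype]

    def has_ecotype(self, ecotype: str) -> bool:
        return ecotype in self.weights


@dataclass
class Parcel:
    """A contiguous area of one ecotype with suitability and trading status.

    ``suitability`` is either a scalar in [0, 1] or a map from
    ``(guild, stage)`` to [0, 1]; guild-resolved parcels need a
    :class:`GuildWeightTable` covering their ecotype to be valued.
    ``terrestrial_class`` labels terrestrial land for balance-sheet
    columns (e.g. ``mainland`` / ``islands``); ``geometry`` is optional
    provenance (e.g. a GeoJSON geometry) and never drives any number.
    """

    parcel_id: str
    ecotype: str
    area: float
    suitability: Suitability
    status: str = "tradable"
    provenance: str = ""
    terrestrial_class: Optional[str] = None
    geometry: Optional[dict] = None


@dataclass
class ParcelState:
    """The valuation-relevant state of a parcel at one side of a transaction."""

    ecotype: str
    area: float
    suitability: Suitability
    status: str = "tradable"
    terrestrial_class: Optional[str] = None

    @staticmethod
    def of(parcel: Parcel) -> "ParcelState":
        return ParcelState(
            ecotype=parcel.ecotype,
            area=parcel.area,
            suitability=copy.deepcopy(parcel.suitability),
            status=parcel.status,
            terrestrial_class=parcel.terrestrial_class,
        )


@dataclass
class ParcelChange:
    """Pre/post record for one parcel touched by a transaction.

    ``pre is None`` means the parcel is created by the transaction;
    ``post is None`` means it is retired outright.  Replaying a journal
    applies the ``post`` states in order.
    """

    parcel_id: str
    pre: Optional[ParcelState]
    post: Optional[ParcelState]


@dataclass
class TradeLeg:
    """One deposit debited by a trade: which account, how much area/PWSA."""

    deposit_ref: str
    area_used: float
    pwsa_used: float


@dataclass
class Transaction:
    """A journal entry, in PWSA units.

    The journal is append-only and totally ordered by ``(timestamp,
    txn_id)``.  ``pwsa_delta`` is the signed change in habitat supply
    caused by the entry's parcel changes (zero for trades, reservations
    and transfers, which move value between statuses or banks without
    changing the supply of the parcels on the ground).
    """

    txn_id: str
    kind: str
    timestamp: _dt.date
    parcel_refs: list[ParcelChange] = field(default_factory=list)
    pwsa_delta: float = 0.0
    offset_ratio: Optional[float] = None
    maturity_date: Optional[_dt.date] = None
    schedule: Optional[str] = None
    withdrawal_ref: Optional[str] = None
    trade_legs: Optional[list[TradeLeg]] = None
    transfer_pwsa: Optional[float] = None
    counterpart: Optional[str] = None
    warning: bool = False
    justification: str = ""
    cost_note: str = ""

    def sort_key(self) -> tuple:
        return (self.timestamp, self.txn_id)


@dataclass
class Objective:
    """A notional per-ecotype target: hectares, percent of total area, or both."""

    area_ha: Optional[float] = None
    percent: Optional[float] = None


@dataclass
class ObjectiveSet:
    """Per-ecotype targets used only for progress reporting."""

    targets: dict[str, Objective] = field(default_factory=dict)


@dataclass
class DepositAccount:
    """A banked deposit: full value at maturity, and the portion already traded.

    ``schedule`` is the maturation rule: ``step`` (the default "hold until
    the cheque clears" — zero value before ``maturity_date``, full value
    after) or ``linear`` (value ramps from the deposit date to maturity).
    """

    txn_id: str
    full_pwsa: float
    deposit_date: _dt.date
    maturity_date: _dt.date
    schedule: str = "step"
    committed_pwsa: float = 0.0
    parcel_ids: list[str] = field(default_factory=list)


@dataclass
class ServiceAreaLedger:
    """A bounded planning area: ecotypes, weights, parcels, objectives, journal.

    ``parcels`` is the current inventory; ``baseline`` is the snapshot the
    journal replays from.  ``boundary_metadata`` (e.g. bounding elevations)
    is stored verbatim and never computed on.
    """

    name: str
    ecotypes: dict[str, EcotypeSpec]
    guild_weights: Optional[GuildWeightTable] = None
    parcels: dict[str, Parcel] = field(default_factory=dict)
    baseline: dict[str, Parcel] = field(default_factory=dict)
    objectives: ObjectiveSet = field(default_factory=ObjectiveSet)
    journal: list[Transaction] = field(default_factory=list)
    accounts: dict[str, DepositAccount] = field(default_factory=dict)
    offset_withdrawals: set[str] = field(default_factory=set)
    boundary_metadata: dict = field(default_factory=dict)
    offset_ratio_default: float = 1.0
    maturation_schedule: str = "step"
    maturation_days: int = 1095

    def __post_init__(self) -> None:
        if not self.baseline and self.parcels:
            self.baseline = copy.deepcopy(self.parcels)

    def ppi(self, ecotype: str) -> float:
        from .errors import UnknownEcotypeError

        try:
            return self.ecotypes[ecotype].ppi
        except KeyError:
            raise UnknownEcotypeError(f"unknown ecotype {ecotype!r}")

    def sorted_journal(self) -> list[Transaction]:
        return sorted(self.journal, key=Transaction.sort_key)


def default_ecotypes() -> dict[str, EcotypeSpec]:
    """The default ecotype table: five aquatic classes plus terrestrial at PPI 0."""
    return {name: EcotypeSpec(name, ppi) for name, ppi in DEFAULT_PPI.items()}


@dataclass(frozen=True)
class Violation:
    """One broken invariant: which entity, which rule, and a message."""

    entity: str
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.entity}: {self.rule}: {self.message}"


def _check_suitability(entity: str, suit: Suitability, out: list[Violation]) -> None:
    if isinstance(suit, Mapping):
        for key, val in suit.items():
            if not (0.0 <= float(val) <= 1.0):
                out.append(
                    Violation(entity, "suitability_range", f"suitability {key} = {val} outside [0, 1]")
                )
    else:
        if not (0.0 <= float(suit) <= 1.0):
            out.append(Violation(entity, "suitability_range", f"suitability {suit} outside [0, 1]"))


def validate_ledger(ledger: ServiceAreaLedger) -> list[Violation]:
    """Check every type invariant and report violations without raising.

    Returns an empty list iff the ledger is internally consistent:
    non-negative PPIs, guild-weight columns summing to 100, parcel areas
    positive with suitabilities in [0, 1] and known ecotypes, percents in
    range, and a journal that is ordered with unique transaction ids.
    """
    out: list[Violation] = []

    for name, spec in ledger.ecotypes.items():
        if spec.ppi < 0:
            out.append(Violation(f"ecotype:{name}", "ppi_nonnegative", f"ppi = {spec.ppi}"))
        if spec.name != name:
            out.append(Violation(f"ecotype:{name}", "name_consistent", f"keyed {name!r}, named {spec.name!r}"))

    if ledger.guild_weights is not None:
        for eco, col in ledger.guild_weights.weights.items():
            total = 0.0
            for key, w in col.items():
                if w < 0:
                    out.append(Violation(f"weights:{eco}", "weight_nonnegative", f"{key} = {w}"))
                total += w
            if abs(total - 100.0) > 1e-9:
                out.append(Violation(f"weights:{eco}", "column_sums_100", f"column sums to {total}"))

    for pid, parcel in ledger.parcels.items():
        entity = f"parcel:{pid}"
        if parcel.parcel_id != pid:
            out.append(Violation(entity, "id_consistent", f"keyed {pid!r}, id {parcel.parcel_id!r}"))
        if parcel.ecotype not in ledger.ecotypes:
            out.append(Violation(entity, "known_ecotype", f"ecotype {parcel.ecotype!r} not in ledger"))
        if not parcel.area > 0:
            out.append(Violation(entity, "area_positive", f"area = {parcel.area}"))
        if parcel.status not in PARCEL_STATUSES:
            out.append(Violation(entity, "valid_status", f"status {parcel.status!r}"))
        _check_suitability(entity, parcel.suitability, out)

    for eco, obj in ledger.objectives.targets.items():
        if obj.percent is not None and not (0.0 <= obj.percent <= 100.0):
            out.append(Violation(f"objective:{eco}", "percent_range", f"percent = {obj.percent}"))
        if obj.area_ha is not None and obj.area_ha < 0:
            out.append(Violation(f"objective:{eco}", "area_nonnegative", f"area_ha = {obj.area_ha}"))

    seen: set[str] = set()
    prev_key = None
    for txn in ledger.journal:
        entity = f"txn:{txn.txn_id}"
        if txn.txn_id in seen:
            out.append(Violation(entity, "unique_txn_id", "duplicate transaction id"))
        seen.add(txn.txn_id)
        if txn.kind not in TRANSACTION_KINDS:
            out.append(Violation(entity, "valid_kind", f"kind {txn.kind!r}"))
        key = txn.sort_key()
        if prev_key is not None and key < prev_key:
            out.append(Violation(entity, "journal_ordered", "journal not ordered by (timestamp, txn_id)"))
        prev_key = key
        if txn.kind == "trade":
            if not txn.withdrawal_ref or txn.withdrawal_ref not in seen:
                out.append(Violation(entity, "trade_refs_withdrawal", "trade must follow the withdrawal it offsets"))
            if not txn.trade_legs:
                out.append(Violation(entity, "trade_refs_deposits", "trade references no deposits"))
            else:
                for leg in txn.trade_legs:
                    if leg.deposit_ref not in seen:
                        out.append(
                            Violation(entity, "trade_refs_deposits", f"deposit {leg.deposit_ref!r} not prior in journal")
                        )
        if txn.kind in ("transfer_in", "transfer_out") and not txn.justification.strip():
            out.append(Violation(entity, "transfer_justified", "transfer lacks a justification"))

    return out
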