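"""Synthetic service areas and the packaged Toronto-nearshore example.

Everything is generated in memory so every module is testable without
downloads.  :func:`make_toronto_fixture` encodes the published worked
example for the Toronto region nearshore integrated planning area: the
standard PPI table and guild-weight matrix, a baseline inventory with one
parcel per (ecotype x quality class) — the coarsest inventory realising
the printed class fractions exactly — notional objectives, and the
three-entry journal (wetland deposit, embayment infill withdrawal, 1:1
offset trade).  :func:`generate_service_area` draws arbitrary synthetic
areas from one seeded random stream.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import numpy as np

from .domain_model import (
    AQUATIC_ECOTYPES,
    QUALITY_CLASS_VALUES,
    EcotypeSpec,
    GuildWeightTable,
    Objective,
    ObjectiveSet,
    Parcel,
    ParcelState,
    ServiceAreaLedger,
    default_ecotypes,
)
from .errors import InfeasibleParamsError, ReserveRuleError
from .ledger import execute_trade, record_deposit, record_withdrawal

#: Baseline ecotype areas (ha) of the Toronto nearshore planning area.
TORONTO_AREAS: dict[str, float] = {
    "rivermouth": 30.0,
    "wetland": 160.0,
    "embayment": 830.0,
    "open_coast": 14000.0,
    "offshore": 440.0,
}
TORONTO_TERRESTRIAL: dict[str, float] = {"mainland": 130.0, "islands": 80.0}

#: Fractions of each ecotype's area in the High/Med/Low quality classes.
TORONTO_CLASS_FRACTIONS: dict[str, dict[str, float]] = {
    "rivermouth": {"High": 0.60, "Med": 0.10, "Low": 0.30},
    "wetland": {"High": 0.80, "Med": 0.15, "Low": 0.05},
    "embayment": {"High": 0.50, "Med": 0.40, "Low": 0.10},
    "open_coast": {"High": 0.65, "Med": 0.25, "Low": 0.10},
    "offshore": {"High": 0.50, "Med": 0.30, "Low": 0.20},
}

#: Notional per-ecotype objectives (ha and percent of the total area).
TORONTO_OBJECTIVES: dict[str, tuple[float, float]] = {
    "terrestrial": (314.0, 2.0),
    "rivermouth": (78.0, 0.5),
    "wetland": (784.0, 5.0),
    "embayment": (1567.0, 10.0),
    "open_coast": (12426.0, 79.3),
    "offshore": (439.0, 2.8),
}

TORONTO_BOUNDARY = {
    "southern_limit_m_asl": 44,
    "northern_limit_m_asl": 77,
    "note": "nearshore planning area bounded by the 44 m ASL lakebed contour "
    "(~30 m depth) and the 77 m ASL upland contour (~100-yr flood level)",
}

#: Journal dates of the worked example: the deposit is constructed a year
#: before its hold clears, the withdrawal and trade follow once matured.
TORONTO_DEPOSIT_DATE = _dt.date(2020, 6, 1)
TORONTO_MATURITY_DATE = _dt.date(2021, 6, 1)
TORONTO_WITHDRAWAL_DATE = _dt.date(2021, 7, 2)
TORONTO_TRADE_DATE = _dt.date(2021, 8, 1)


def make_toronto_fixture(
    unit_suitability: bool = False, with_journal: bool = True
) -> ServiceAreaLedger:
    """The packaged Toronto-nearshore example ledger.

    With ``unit_suitability=False`` (default) parcel suitabilities are
    the class representatives 0.75/0.50/0.25, realising the published
    baseline quality block exactly.  With ``unit_suitability=True`` every
    parcel is valued at suitability 1.0 — the variant used by the
    published supply balance sheet, whose baseline total PWSA is 8305.
    ``with_journal`` appends the worked three-transaction journal
    (deposit +, withdrawal -, 1:1 trade).
    """
    parcels: dict[str, Parcel] = {}
    for label, area in TORONTO_TERRESTRIAL.items():
        parcels[label] = Parcel(
            parcel_id=label,
            ecotype="terrestrial",
            area=area,
            suitability=0.0,
            provenance="natural",
            terrestrial_class=label,
        )
    for eco in AQUATIC_ECOTYPES:
        for label, fraction in TORONTO_CLASS_FRACTIONS[eco].items():
            pid = f"{eco}-{label.lower()}"
            suit = 1.0 if unit_suitability else QUALITY_CLASS_VALUES[label]
            parcels[pid] = Parcel(
                parcel_id=pid,
                ecotype=eco,
                area=TORONTO_AREAS[eco] * fraction,
                suitability=suit,
                provenance="natural",
            )

    ledger = ServiceAreaLedger(
        name="toronto-nearshore",
        ecotypes=default_ecotypes(),
        guild_weights=GuildWeightTable(),
        parcels=parcels,
        objectives=ObjectiveSet(
            targets={
                eco: Objective(area_ha=ha, percent=pct)
                for eco, (ha, pct) in TORONTO_OBJECTIVES.items()
            }
        ),
        boundary_metadata=dict(TORONTO_BOUNDARY),
        offset_ratio_default=1.0,
        maturation_schedule="step",
        maturation_days=365,
    )

    if with_journal:
        suit = 1.0 if unit_suitability else 0.75
        deposit = record_deposit(
            ledger,
            created_parcels=[
                Parcel("bank-wetland", "wetland", 1.0, suit, provenance="created")
            ],
            converted_from=[("mainland", 1.0)],
            maturity=TORONTO_MATURITY_DATE,
            on=TORONTO_DEPOSIT_DATE,
            schedule="step",
        )
        withdrawal = record_withdrawal(
            ledger,
            impacts=[
                (
                    "embayment-med",
                    1.0,
                    ParcelState(
                        ecotype="terrestrial",
                        area=1.0,
                        suitability=0.0,
                        terrestrial_class="mainland",
                    ),
                )
            ],
            on=TORONTO_WITHDRAWAL_DATE,
        )
        execute_trade(
            ledger,
            withdrawal_ref=withdrawal.txn_id,
            deposit_refs=[deposit.txn_id],
            offset_ratio=1.0,
            on=TORONTO_TRADE_DATE,
        )
    return ledger


SuitabilitySpec = Union[Mapping[str, float], tuple[float, float]]


@dataclass
class FixtureParams:
    """Parameters of a synthetic service area.

    ``suitability`` is either a class-fraction map (``{"High": .5,
    "Med": .3, "Low": .2}``; parcels take the representative class
    values) or a ``("beta", a, b)``-style tuple ``(a, b)`` drawing
    suitabilities from a Beta(a, b) distribution.  ``kind_mix`` gives the
    relative weight of deposits / withdrawals / trades among the
    generated transactions.
    """

    seed: int = 0
    areas: dict[str, float] = field(
        default_factory=lambda: {
            "terrestrial": 50.0,
            "rivermouth": 10.0,
            "wetland": 40.0,
            "embayment": 100.0,
            "open_coast": 500.0,
            "offshore": 100.0,
        }
    )
    n_parcels: Union[int, dict[str, int]] = 4
    suitability: SuitabilitySpec = field(
        default_factory=lambda: {"High": 0.5, "Med": 0.3, "Low": 0.2}
    )
    reserve_fraction: float = 0.0
    n_transactions: int = 0
    kind_mix: dict[str, float] = field(
        default_factory=lambda: {"deposit": 0.4, "withdrawal": 0.4, "trade": 0.2}
    )
    start: _dt.date = _dt.date(2024, 1, 1)


def _validate_params(params: FixtureParams) -> None:
    if not (0.0 <= params.reserve_fraction <= 1.0):
        raise InfeasibleParamsError(f"reserve_fraction {params.reserve_fraction} outside [0, 1]")
    if isinstance(params.suitability, Mapping):
        total = sum(params.suitability.values())
        if any(v < 0 for v in params.suitability.values()) or abs(total - 1.0) > 1e-9:
            raise InfeasibleParamsError(f"class fractions must be in [0,1] and sum to 1, got {params.suitability}")
    mix_total = sum(params.kind_mix.values())
    if params.n_transactions > 0 and mix_total <= 0:
        raise InfeasibleParamsError("kind_mix must have positive total weight")
    for eco, area in params.areas.items():
        n = params.n_parcels[eco] if isinstance(params.n_parcels, dict) else params.n_parcels
        if area > 0 and n < 1:
            raise InfeasibleParamsError(f"ecotype {eco!r}: positive area over zero parcels")


def draw_suitabilities(
    spec: SuitabilitySpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n suitabilities from a class-fraction or Beta(a, b) spec."""
    if isinstance(spec, Mapping):
        labels = list(spec.keys())
        probs = np.array([spec[l] for l in labels], dtype=float)
        picks = rng.choice(len(labels), size=n, p=probs / probs.sum())
        return np.array([QUALITY_CLASS_VALUES[labels[i]] for i in picks])
    a, b = spec
    return rng.beta(a, b, size=n)


def generate_service_area(params: FixtureParams) -> ServiceAreaLedger:
    """Generate a deterministic synthetic ledger from one seeded stream.

    Parcel areas per ecotype are a Dirichlet split of the requested
    total (realised totals match the request to float precision);
    suitabilities follow the configured spec; a ``reserve_fraction`` of
    parcels is set aside before any trading.  Transactions are then
    applied through the ordinary ledger operations: deposits first (so
    trades can mature), then withdrawals, then trades — if no tradable
    parcel is available (e.g. everything is reserved) the attempt raises
    :class:`ReserveRuleError` exactly as a manual attempt would.
    """
    _validate_params(params)
    rng = np.random.default_rng(params.seed)

    parcels: dict[str, Parcel] = {}
    for eco, total in params.areas.items():
        if total <= 0:
            continue
        n = params.n_parcels[eco] if isinstance(params.n_parcels, dict) else params.n_parcels
        shares = rng.dirichlet(np.full(n, 5.0)) * total
        suits = (
            np.zeros(n) if eco == "terrestrial" else draw_suitabilities(params.suitability, n, rng)
        )
        reserved = rng.random(n) < params.reserve_fraction
        for i in range(n):
            pid = f"{eco}-{i:03d}"
            parcels[pid] = Parcel(
                parcel_id=pid,
                ecotype=eco,
                area=float(shares[i]),
                suitability=float(suits[i]),
                status="reserve" if reserved[i] else "tradable",
                provenance="synthetic",
                terrestrial_class="mainland" if eco == "terrestrial" else None,
            )

    ledger = ServiceAreaLedger(
        name=f"synthetic-{params.seed}",
        ecotypes=default_ecotypes(),
        guild_weights=GuildWeightTable(),
        parcels=parcels,
        maturation_schedule="step",
        maturation_days=60,
    )

    if params.n_transactions > 0:
        _generate_transactions(ledger, params, rng)
    return ledger


def _pick_tradable(ledger, rng, aquatic: bool, min_area: float = 1e-3):
    candidates = sorted(
        p.parcel_id
        for p in ledger.parcels.values()
        if p.status == "tradable"
        and p.area >= min_area
        and ((p.ecotype != "terrestrial") == aquatic)
    )
    if not candidates:
        kind = "aquatic" if aquatic else "terrestrial"
        raise ReserveRuleError(
            f"no tradable {kind} parcel available (reserves are not available for trading)"
        )
    return ledger.parcels[candidates[rng.integers(len(candidates))]]


def _generate_transactions(ledger, params: FixtureParams, rng: np.random.Generator) -> None:
    mix_total = sum(params.kind_mix.values())
    counts = {
        kind: int(round(params.n_transactions * w / mix_total))
        for kind, w in params.kind_mix.items()
    }
    date = params.start
    deposits = []
    for _ in range(counts.get("deposit", 0)):
        source = _pick_tradable(ledger, rng, aquatic=False)
        take = min(source.area * 0.25, 2.0)
        eco = ("wetland", "embayment", "rivermouth")[int(rng.integers(3))]
        suit = float(rng.uniform(0.5, 1.0))
        txn = record_deposit(
            ledger,
            created_parcels=[
                Parcel(f"dep-parcel-{len(deposits)}", eco, take, suit, provenance="created")
            ],
            converted_from=[(source.parcel_id, take)],
            maturity=date + _dt.timedelta(days=ledger.maturation_days),
            on=date,
        )
        deposits.append(txn)
        date += _dt.timedelta(days=7)
    date += _dt.timedelta(days=ledger.maturation_days)  # let the holds clear
    withdrawals = []
    for _ in range(counts.get("withdrawal", 0)):
        target = _pick_tradable(ledger, rng, aquatic=True)
        take = min(target.area * 0.1, 1.0)
        post = ParcelState(
            ecotype="terrestrial", area=take, suitability=0.0, terrestrial_class="mainland"
        )
        withdrawals.append(
            record_withdrawal(ledger, impacts=[(target.parcel_id, take, post)], on=date)
        )
        date += _dt.timedelta(days=7)
    open_withdrawals = [w for w in withdrawals if w.pwsa_delta < 0]
    for _ in range(counts.get("trade", 0)):
        if not open_withdrawals:
            break
        withdrawal = open_withdrawals.pop(0)
        try:
            execute_trade(ledger, withdrawal.txn_id, on=date)
        except Exception:
            break  # bank exhausted; remaining losses stay uncovered liabilities
        date += _dt.timedelta(days=7)
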