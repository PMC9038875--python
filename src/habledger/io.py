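"""File formats: parcel inventories, configuration, and journal persistence.

Formats are deliberately plain:

* parcel inventories — CSV (UTF-8, decimal point, columns ``parcel_id,
  ecotype, area_ha, status`` plus either a scalar ``suitability`` column
  or nine ``suit_<guild>_<stage>`` columns) or a GeoJSON
  FeatureCollection whose features carry the same fields as properties.
  Geometry is stored as provenance only; ``area_ha`` is always the
  authoritative area — no projection or CRS arithmetic happens here.
* configuration — YAML or JSON: ecotype/PPI table, guild weights,
  maturation defaults, default offset ratio, objectives, boundary
  metadata.
* journal — append-only JSON lines, one transaction per line, dates in
  ISO form; reloading refuses corrupted or out-of-order records with the
  offending line number.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd
import yaml

from .domain_model import (
    DEFAULT_PPI,
    LIFE_STAGES,
    THERMAL_GUILDS,
    TRANSACTION_KINDS,
    EcotypeSpec,
    GuildWeightTable,
    Objective,
    ObjectiveSet,
    Parcel,
    ParcelChange,
    ParcelState,
    ServiceAreaLedger,
    TradeLeg,
    Transaction,
    default_ecotypes,
)
from .errors import JournalFormatError, ParcelInputError
from .ledger import rebuild

_SUIT_COLUMNS = [f"suit_{g}_{s}" for g in THERMAL_GUILDS for s in LIFE_STAGES]
_REQUIRED = ["parcel_id", "ecotype", "area_ha", "status"]

PathLike = Union[str, Path]


# ---------------------------------------------------------------- parcels

def _parcel_from_record(
    record: Mapping, where: str, known_ecotypes, errors: list[str]
) -> Optional[Parcel]:
    missing = [c for c in _REQUIRED if record.get(c) in (None, "")]
    has_scalar = record.get("suitability") not in (None, "")
    has_guild = all(record.get(c) not in (None, "") for c in _SUIT_COLUMNS)
    if not has_scalar and not has_guild:
        missing.append("suitability (or the nine suit_<guild>_<stage> columns)")
    if missing:
        errors.append(f"{where}: missing column(s) {', '.join(missing)}")
        return None
    ecotype = str(record["ecotype"])
    if known_ecotypes is not None and ecotype not in known_ecotypes:
        errors.append(f"{where}: unknown ecotype {ecotype!r}")
        return None
    suitability: Union[float, dict]
    if has_guild and not has_scalar:
        suitability = {
            (g, s): float(record[f"suit_{g}_{s}"]) for g in THERMAL_GUILDS for s in LIFE_STAGES
        }
    else:
        suitability = float(record["suitability"])
    tclass = record.get("terrestrial_class")
    return Parcel(
        parcel_id=str(record["parcel_id"]),
        ecotype=ecotype,
        area=float(record["area_ha"]),
        suitability=suitability,
        status=str(record["status"]),
        provenance=str(record.get("provenance") or ""),
        terrestrial_class=str(tclass) if tclass not in (None, "") else None,
    )


def read_parcels(
    path: PathLike, format: Optional[str] = None, known_ecotypes=None
) -> list[Parcel]:
    """Read a validated parcel inventory from CSV or GeoJSON.

    ``format`` is inferred from the suffix when omitted.  All schema
    problems (missing columns, unknown ecotype labels, duplicate ids) are
    collected and raised together as :class:`ParcelInputError`, each
    naming the offending row or feature.
    """
    path = Path(path)
    fmt = format or ("geojson" if path.suffix.lower() in (".geojson", ".json") else "csv")
    errors: list[str] = []
    parcels: list[Parcel] = []

    if fmt == "csv":
        frame = pd.read_csv(path, dtype={"parcel_id": str}, encoding="utf-8")
        frame = frame.where(pd.notna(frame), None)
        for idx, record in enumerate(frame.to_dict(orient="records")):
            parcel = _parcel_from_record(record, f"row {idx + 2}", known_ecotypes, errors)
            if parcel is not None:
                parcels.append(parcel)
    elif fmt == "geojson":
        with open(path, encoding="utf-8") as handle:
            doc = json.load(handle)
        if doc.get("type") != "FeatureCollection":
            raise ParcelInputError(f"{path}: not a GeoJSON FeatureCollection")
        for idx, feature in enumerate(doc.get("features", [])):
            where = f"feature {idx}"
            props = feature.get("properties") or {}
            if props.get("area_ha") in (None, ""):
                errors.append(f"{where}: missing area_ha property")
                continue
            parcel = _parcel_from_record(props, where, known_ecotypes, errors)
            if parcel is not None:
                parcel.geometry = feature.get("geometry")
                parcels.append(parcel)
    else:
        raise ValueError(f"unknown format {fmt!r}")

    seen: dict[str, int] = {}
    for i, parcel in enumerate(parcels):
        if parcel.parcel_id in seen:
            errors.append(
                f"duplicate parcel_id {parcel.parcel_id!r} (records {seen[parcel.parcel_id]} and {i})"
            )
        else:
            seen[parcel.parcel_id] = i
    if errors:
        raise ParcelInputError(f"{path}:\n  " + "\n  ".join(errors))
    return parcels


def write_parcels_csv(parcels, path: PathLike) -> None:
    """Write an inventory in the canonical CSV dialect."""
    records = []
    guild_resolved = any(isinstance(p.suitability, Mapping) for p in parcels)
    for p in parcels:
        rec = {
            "parcel_id": p.parcel_id,
            "ecotype": p.ecotype,
            "area_ha": p.area,
            "status": p.status,
            "provenance": p.provenance,
            "terrestrial_class": p.terrestrial_class,
        }
        if isinstance(p.suitability, Mapping):
            for (g, s), v in p.suitability.items():
                rec[f"suit_{g}_{s}"] = v
        else:
            rec["suitability"] = p.suitability
            if guild_resolved:
                pass  # mixed inventories keep both column families
        records.append(rec)
    pd.DataFrame.from_records(records).to_csv(path, index=False, encoding="utf-8")


# ---------------------------------------------------------------- journal

def _suit_to_json(suit):
    if isinstance(suit, Mapping):
        return {f"{g}:{s}": float(v) for (g, s), v in suit.items()}
    return float(suit)


def _suit_from_json(val):
    if isinstance(val, dict):
        return {tuple(k.split(":", 1)): float(v) for k, v in val.items()}
    return float(val)


def _state_to_json(state: Optional[ParcelState]):
    if state is None:
        return None
    return {
        "ecotype": state.ecotype,
        "area": state.area,
        "suitability": _suit_to_json(state.suitability),
        "status": state.status,
        "terrestrial_class": state.terrestrial_class,
    }


def _state_from_json(doc) -> Optional[ParcelState]:
    if doc is None:
        return None
    return ParcelState(
        ecotype=doc["ecotype"],
        area=float(doc["area"]),
        suitability=_suit_from_json(doc["suitability"]),
        status=doc.get("status", "tradable"),
        terrestrial_class=doc.get("terrestrial_class"),
    )


def transaction_to_dict(txn: Transaction) -> dict:
    doc = {
        "txn_id": txn.txn_id,
        "kind": txn.kind,
        "timestamp": txn.timestamp.isoformat(),
        "parcel_refs": [
            {"parcel_id": r.parcel_id, "pre": _state_to_json(r.pre), "post": _state_to_json(r.post)}
            for r in txn.parcel_refs
        ],
        "pwsa_delta": txn.pwsa_delta,
    }
    if txn.offset_ratio is not None:
        doc["offset_ratio"] = txn.offset_ratio
    if txn.maturity_date is not None:
        doc["maturity_date"] = txn.maturity_date.isoformat()
    if txn.schedule is not None:
        doc["schedule"] = txn.schedule
    if txn.withdrawal_ref is not None:
        doc["withdrawal_ref"] = txn.withdrawal_ref
    if txn.trade_legs is not None:
        doc["trade_legs"] = [
            {"deposit_ref": l.deposit_ref, "area_used": l.area_used, "pwsa_used": l.pwsa_used}
            for l in txn.trade_legs
        ]
    if txn.transfer_pwsa is not None:
        doc["transfer_pwsa"] = txn.transfer_pwsa
    if txn.counterpart is not None:
        doc["counterpart"] = txn.counterpart
    if txn.warning:
        doc["warning"] = True
    if txn.justification:
        doc["justification"] = txn.justification
    if txn.cost_note:
        doc["cost_note"] = txn.cost_note
    return doc


def transaction_from_dict(doc: Mapping) -> Transaction:
    kind = doc.get("kind")
    if kind not in TRANSACTION_KINDS:
        raise JournalFormatError(f"unknown transaction kind {kind!r}")
    legs = None
    if "trade_legs" in doc:
        legs = [
            TradeLeg(l["deposit_ref"], float(l["area_used"]), float(l["pwsa_used"]))
            for l in doc["trade_legs"]
        ]
    return Transaction(
        txn_id=str(doc["txn_id"]),
        kind=kind,
        timestamp=_dt.date.fromisoformat(doc["timestamp"]),
        parcel_refs=[
            ParcelChange(r["parcel_id"], _state_from_json(r.get("pre")), _state_from_json(r.get("post")))
            for r in doc.get("parcel_refs", [])
        ],
        pwsa_delta=float(doc.get("pwsa_delta", 0.0)),
        offset_ratio=doc.get("offset_ratio"),
        maturity_date=_dt.date.fromisoformat(doc["maturity_date"]) if doc.get("maturity_date") else None,
        schedule=doc.get("schedule"),
        withdrawal_ref=doc.get("withdrawal_ref"),
        trade_legs=legs,
        transfer_pwsa=doc.get("transfer_pwsa"),
        counterpart=doc.get("counterpart"),
        warning=bool(doc.get("warning", False)),
        justification=doc.get("justification", ""),
        cost_note=doc.get("cost_note", ""),
    )


def write_journal(journal, path: PathLike) -> None:
    """Write a journal as JSON lines, one transaction per line."""
    with open(path, "w", encoding="utf-8") as handle:
        for txn in journal:
            handle.write(json.dumps(transaction_to_dict(txn)) + "\n")


def append_journal(txn: Transaction, path: PathLike) -> None:
    with open(path, "a", encoding="utf-8") as handle:
        handle.write(json.dumps(transaction_to_dict(txn)) + "\n")


def read_journal(path: PathLike) -> list[Transaction]:
    """Reload a JSON-lines journal, refusing corrupt or out-of-order lines."""
    out: list[Transaction] = []
    prev_key = None
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            try:
                doc = json.loads(line)
                txn = transaction_from_dict(doc)
            except JournalFormatError as exc:
                raise JournalFormatError(f"{path}: line {lineno}: {exc}") from None
            except (ValueError, KeyError, TypeError) as exc:
                raise JournalFormatError(f"{path}: line {lineno}: corrupted record ({exc})") from None
            key = txn.sort_key()
            if prev_key is not None and key < prev_key:
                raise JournalFormatError(
                    f"{path}: line {lineno}: journal out of order ({txn.txn_id} at {txn.timestamp})"
                )
            prev_key = key
            out.append(txn)
    return out


# ----------------------------------------------------------------- config

@dataclass
class LedgerConfig:
    """Service-area configuration: everything but the parcels and journal."""

    name: str = "service-area"
    ecotypes: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PPI))
    guild_weights: Optional[dict[str, dict[tuple[str, str], float]]] = None
    maturation_schedule: str = "step"
    maturation_days: int = 1095
    offset_ratio_default: float = 1.0
    objectives: dict[str, dict] = field(default_factory=dict)
    boundary_metadata: dict = field(default_factory=dict)


def default_config() -> LedgerConfig:
    """The packaged defaults: the standard PPI table and guild-weight matrix."""
    return LedgerConfig(guild_weights=GuildWeightTable().weights)


def load_config(path: PathLike) -> LedgerConfig:
    with open(path, encoding="utf-8") as handle:
        doc = yaml.safe_load(handle) or {}
    weights = None
    if doc.get("guild_weights"):
        weights = {
            eco: {tuple(k.split("_", 1)): float(v) for k, v in col.items()}
            for eco, col in doc["guild_weights"].items()
        }
    return LedgerConfig(
        name=doc.get("name", "service-area"),
        ecotypes={k: float(v) for k, v in (doc.get("ecotypes") or dict(DEFAULT_PPI)).items()},
        guild_weights=weights,
        maturation_schedule=(doc.get("maturation") or {}).get("schedule", "step"),
        maturation_days=int((doc.get("maturation") or {}).get("days", 1095)),
        offset_ratio_default=float(doc.get("offset_ratio", 1.0)),
        objectives=doc.get("objectives") or {},
        boundary_metadata=doc.get("boundary") or {},
    )


def save_config(config: LedgerConfig, path: PathLike) -> None:
    doc = {
        "name": config.name,
        "boundary": config.boundary_metadata,
        "ecotypes": config.ecotypes,
        "maturation": {"schedule": config.maturation_schedule, "days": config.maturation_days},
        "offset_ratio": config.offset_ratio_default,
        "objectives": config.objectives,
    }
    if config.guild_weights:
        doc["guild_weights"] = {
            eco: {f"{g}_{s}": v for (g, s), v in col.items()}
            for eco, col in config.guild_weights.items()
        }
    with open(path, "w", encoding="utf-8") as handle:
        yaml.safe_dump(doc, handle, sort_keys=False)


def build_ledger(config: LedgerConfig, parcels) -> ServiceAreaLedger:
    """Assemble a ledger skeleton from a config plus a parcel inventory."""
    objectives = ObjectiveSet(
        targets={
            eco: Objective(area_ha=spec.get("area_ha"), percent=spec.get("percent"))
            for eco, spec in config.objectives.items()
        }
    )
    return ServiceAreaLedger(
        name=config.name,
        ecotypes={name: EcotypeSpec(name, ppi) for name, ppi in config.ecotypes.items()},
        guild_weights=GuildWeightTable(weights=config.guild_weights) if config.guild_weights else None,
        parcels={p.parcel_id: p for p in parcels},
        objectives=objectives,
        boundary_metadata=config.boundary_metadata,
        offset_ratio_default=config.offset_ratio_default,
        maturation_schedule=config.maturation_schedule,
        maturation_days=config.maturation_days,
    )


# ------------------------------------------------------- ledger directory

def save_ledger(ledger: ServiceAreaLedger, directory: PathLike) -> None:
    """Persist a ledger as a directory: config.yaml, parcels.csv, journal.jsonl.

    The parcel file holds the *baseline* inventory; the current state is
    always the baseline replayed through the journal.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    config = LedgerConfig(
        name=ledger.name,
        ecotypes={name: spec.ppi for name, spec in ledger.ecotypes.items()},
        guild_weights=ledger.guild_weights.weights if ledger.guild_weights else None,
        maturation_schedule=ledger.maturation_schedule,
        maturation_days=ledger.maturation_days,
        offset_ratio_default=ledger.offset_ratio_default,
        objectives={
            eco: {k: v for k, v in (("area_ha", o.area_ha), ("percent", o.percent)) if v is not None}
            for eco, o in ledger.objectives.targets.items()
        },
        boundary_metadata=ledger.boundary_metadata,
    )
    save_config(config, directory / "config.yaml")
    write_parcels_csv(list(ledger.baseline.values()), directory / "parcels.csv")
    write_journal(ledger.sorted_journal(), directory / "journal.jsonl")


def load_ledger(directory: PathLike) -> ServiceAreaLedger:
    """Reload a ledger directory and replay its journal to the current state."""
    directory = Path(directory)
    config = load_config(directory / "config.yaml")
    parcels = read_parcels(directory / "parcels.csv", known_ecotypes=set(config.ecotypes))
    ledger = build_ledger(config, parcels)
    journal_path = directory / "journal.jsonl"
    if journal_path.exists():
        ledger.journal = read_journal(journal_path)
        ledger = rebuild(ledger)
    return ledger
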