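"""Balance sheets and progress-toward-objective reports.

A balance sheet rolls the ledger up into the familiar supply-statement
shape: a baseline row, one delta row per transaction kind, the bank
remainder (matured, uncommitted deposit value), and the updated supply.
Columns are the terrestrial classes (e.g. mainland / islands), the
aquatic ecotypes in fixed order, and a grand total.  All totals are
computed at full precision; rounding (areas to 1 decimal, PWSA to 2)
happens only in rendering and never feeds back into computation.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .domain_model import (
    AQUATIC_ECOTYPES,
    ObjectiveSet,
    Parcel,
    ServiceAreaLedger,
)
from .errors import LedgerError
from .ledger import available_value, rebuild, state_pwsa
from .valuation import effective_suitability

_KIND_ORDER = ("deposit", "withdrawal", "trade", "reservation", "transfer_out", "transfer_in")
_KIND_LABELS = {
    "deposit": "Deposit",
    "withdrawal": "Withdrawal",
    "trade": "Trade",
    "reservation": "Reservation",
    "transfer_out": "Transfer out",
    "transfer_in": "Transfer in",
}


def _column_of(state) -> str:
    if state.ecotype == "terrestrial":
        return state.terrestrial_class or "terrestrial"
    return state.ecotype


@dataclass
class SheetRow:
    """One balance-sheet row: a label with per-column PWSA and area values."""

    label: str
    pwsa: dict[str, float] = field(default_factory=dict)
    area: dict[str, float] = field(default_factory=dict)


@dataclass
class BalanceSheet:
    """Per-ecotype supply statement: baseline, transaction deltas, bank, updated."""

    columns: list[str]
    rows: list[SheetRow]
    as_of: Optional[_dt.date] = None

    def row(self, label: str) -> SheetRow:
        for r in self.rows:
            if r.label == label:
                return r
        raise KeyError(label)

    def to_dataframe(self) -> pd.DataFrame:
        """Two DataFrame rows per sheet row: PWSA then area, full precision."""
        records, index = [], []
        for r in self.rows:
            index.append((r.label, "PWSA"))
            records.append([r.pwsa.get(c, 0.0) for c in self.columns])
            index.append((r.label, "Area (ha)"))
            records.append([r.area.get(c, 0.0) for c in self.columns])
        return pd.DataFrame(
            records,
            index=pd.MultiIndex.from_tuples(index, names=["row", "units"]),
            columns=self.columns,
        )

    def render_text(self) -> str:
        """Plain-text rendering with the reporting precision (1 dp areas, 2 dp PWSA)."""
        df = self.to_dataframe()
        shown = df.copy()
        for (label, unit) in df.index:
            digits = 2 if unit == "PWSA" else 1
            shown.loc[(label, unit)] = df.loc[(label, unit)].round(digits)
        title = f"Habitat supply balance sheet"
        if self.as_of:
            title += f" (as of {self.as_of.isoformat()})"
        return title + "\n" + shown.to_string(float_format=lambda v: f"{v:,.2f}".rstrip("0").rstrip("."))

    def to_csv(self) -> str:
        return self.to_dataframe().to_csv()

    def to_json(self) -> str:
        payload = {
            "as_of": self.as_of.isoformat() if self.as_of else None,
            "columns": self.columns,
            "rows": [
                {"label": r.label, "pwsa": r.pwsa, "area": r.area} for r in self.rows
            ],
        }
        return json.dumps(payload, indent=2)


def _rollup(parcels, ledger: ServiceAreaLedger) -> tuple[dict[str, float], dict[str, float]]:
    pwsa: dict[str, float] = {}
    area: dict[str, float] = {}
    for parcel in parcels:
        if parcel.status == "retired":
            continue
        col = _column_of(parcel)
        s_eff = effective_suitability(parcel, ledger.guild_weights)
        area[col] = area.get(col, 0.0) + parcel.area
        pwsa[col] = pwsa.get(col, 0.0) + parcel.area * s_eff * ledger.ppi(parcel.ecotype)
    return pwsa, area


def _sheet_columns(ledger: ServiceAreaLedger, current: dict[str, Parcel]) -> list[str]:
    terrestrial: list[str] = []
    for inventory in (ledger.baseline, current):
        for parcel in inventory.values():
            if parcel.ecotype == "terrestrial":
                label = parcel.terrestrial_class or "terrestrial"
                if label not in terrestrial:
                    terrestrial.append(label)
    aquatic = [e for e in AQUATIC_ECOTYPES if e in ledger.ecotypes]
    aquatic += sorted(
        e for e in ledger.ecotypes if e not in aquatic and e != "terrestrial"
    )
    return terrestrial + aquatic


def balance_sheet(ledger: ServiceAreaLedger, on: Optional[_dt.date] = None) -> BalanceSheet:
    """Build the supply balance sheet at a date.

    The updated row is the valuation of the replayed inventory and must
    equal baseline plus the sum of the delta rows, column by column; the
    sheet raises :class:`LedgerError` if they disagree beyond float
    tolerance (they cannot, unless the journal was edited by hand).
    """
    state = rebuild(ledger)
    journal = state.sorted_journal()
    if on is None:
        on = journal[-1].timestamp if journal else _dt.date.today()

    columns = _sheet_columns(ledger, state.parcels)
    base_pwsa, base_area = _rollup(ledger.baseline.values(), ledger)
    rows = [SheetRow("Baseline supply", pwsa=base_pwsa, area=base_area)]

    deltas: dict[str, SheetRow] = {}
    for txn in journal:
        if txn.timestamp > on:
            break
        row = deltas.setdefault(txn.kind, SheetRow(_KIND_LABELS.get(txn.kind, txn.kind)))
        for ref in txn.parcel_refs:
            if ref.pre is not None:
                col = _column_of(ref.pre)
                row.pwsa[col] = row.pwsa.get(col, 0.0) - state_pwsa(ledger, ref.pre)
                row.area[col] = row.area.get(col, 0.0) - ref.pre.area
            if ref.post is not None:
                col = _column_of(ref.post)
                row.pwsa[col] = row.pwsa.get(col, 0.0) + state_pwsa(ledger, ref.post)
                row.area[col] = row.area.get(col, 0.0) + ref.post.area
    for kind in _KIND_ORDER:
        if kind in deltas:
            rows.append(deltas[kind])

    bank = SheetRow("Bank remainder")
    for account in state.accounts.values():
        if on < account.deposit_date:
            continue
        avail = max(0.0, available_value(account, on))
        if avail <= 0:
            continue
        holdings = []
        for pid in account.parcel_ids:
            parcel = state.parcels.get(pid)
            if parcel is None or parcel.status != "tradable":
                continue
            holdings.append(parcel)
        total_pwsa = sum(
            p.area * effective_suitability(p, ledger.guild_weights) * ledger.ppi(p.ecotype)
            for p in holdings
        )
        if total_pwsa > 0:
            frac = min(1.0, avail / total_pwsa)
            for p in holdings:
                col = _column_of(p)
                p_pwsa = p.area * effective_suitability(p, ledger.guild_weights) * ledger.ppi(p.ecotype)
                bank.pwsa[col] = bank.pwsa.get(col, 0.0) + p_pwsa * frac
                bank.area[col] = bank.area.get(col, 0.0) + p.area * frac
        leftover = avail - min(avail, total_pwsa)
        if leftover > 1e-12:
            # transferred-in credit carries value but no parcels on the ground
            bank.pwsa["(unallocated)"] = bank.pwsa.get("(unallocated)", 0.0) + leftover
    rows.append(bank)

    upd_pwsa, upd_area = _rollup(state.parcels.values(), ledger)
    updated = SheetRow("Updated supply", pwsa=upd_pwsa, area=upd_area)
    rows.append(updated)

    for col in columns:
        recon_p = base_pwsa.get(col, 0.0) + sum(d.pwsa.get(col, 0.0) for d in deltas.values())
        recon_a = base_area.get(col, 0.0) + sum(d.area.get(col, 0.0) for d in deltas.values())
        if abs(recon_p - upd_pwsa.get(col, 0.0)) > 1e-6 or abs(recon_a - upd_area.get(col, 0.0)) > 1e-6:
            raise LedgerError(f"balance sheet does not reconcile in column {col!r}")

    if "(unallocated)" in bank.pwsa:
        columns = columns + ["(unallocated)"]
    for r in rows:
        r.pwsa["total"] = sum(r.pwsa.get(c, 0.0) for c in columns)
        r.area["total"] = sum(r.area.get(c, 0.0) for c in columns)
    return BalanceSheet(columns=columns + ["total"], rows=rows, as_of=on)


def progress_report(
    ledger: ServiceAreaLedger, objectives: Optional[ObjectiveSet] = None
) -> pd.DataFrame:
    """Per-ecotype gap table against the (notional) objectives.

    Columns: current hectares, current percent of the grand total area
    (terrestrial included), target hectares and percent, and the absolute
    and percent gaps (target minus current).  Objective entries are
    displayed as given, never re-normalised.
    """
    objectives = objectives or ledger.objectives
    if not objectives.targets:
        raise ValueError("objectives must cover at least one ecotype")
    current: dict[str, float] = {}
    for parcel in ledger.parcels.values():
        if parcel.status == "retired":
            continue
        current[parcel.ecotype] = current.get(parcel.ecotype, 0.0) + parcel.area
    grand_total = sum(current.values())

    records = []
    for eco, obj in objectives.targets.items():
        cur = current.get(eco, 0.0)
        target = obj.area_ha
        if target is None and obj.percent is not None:
            target = obj.percent / 100.0 * grand_total
        cur_pct = 100.0 * cur / grand_total if grand_total else float("nan")
        tgt_pct = obj.percent
        if tgt_pct is None and target is not None and grand_total:
            tgt_pct = 100.0 * target / grand_total
        records.append(
            {
                "ecotype": eco,
                "current_ha": cur,
                "current_pct": cur_pct,
                "target_ha": target,
                "target_pct": tgt_pct,
                "gap_ha": None if target is None else target - cur,
                "gap_pct": None if tgt_pct is None else tgt_pct - cur_pct,
            }
        )
    return pd.DataFrame.from_records(records).set_index("ecotype")
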