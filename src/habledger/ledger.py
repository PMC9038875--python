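"""Transaction semantics: deposits, withdrawals, trades, reserves, transfers.

The engine mirrors double-entry banking practice.  Habitat creation or
improvement is a *deposit* that opens an account whose PWSA value matures
over time ("a hold until the cheque clears"); an unavoidable development
impact is a *withdrawal*; a *trade* debits matured deposit value against
a withdrawal at an offset ratio r >= 1, moving the used deposit area into
the natural capital reserves; *transfers* move matured value between
service areas and always carry a warning flag.

Every state change flows through :func:`apply_transaction`, the same
routine :func:`replay` uses, so the live inventory and a journal replay
from the baseline can never disagree.

Hectares are conserved by construction: conversions (land -> wetland,
embayment -> infill) move area between ecotypes, never create or destroy
it.
"""

from __future__ import annotations

import copy
import datetime as _dt
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .domain_model import (
    DepositAccount,
    Parcel,
    ParcelChange,
    ParcelState,
    ServiceAreaLedger,
    TradeLeg,
    Transaction,
)
from .errors import (
    DoubleOffsetError,
    InsufficientBalanceError,
    LedgerError,
    NonPositiveGainError,
    ReserveRuleError,
    RetiredParcelError,
    TransferError,
)
from .valuation import Valuation, effective_suitability, valuate

_TOL = 1e-9


def state_pwsa(ledger: ServiceAreaLedger, state: Optional[ParcelState]) -> float:
    """PWSA of one parcel state: area x effective suitability x PPI."""
    if state is None:
        return 0.0
    probe = Parcel(
        parcel_id="<state>",
        ecotype=state.ecotype,
        area=state.area,
        suitability=state.suitability,
    )
    return probe.area * effective_suitability(probe, ledger.guild_weights) * ledger.ppi(state.ecotype)


def _refs_pwsa_delta(ledger: ServiceAreaLedger, refs: Iterable[ParcelChange]) -> float:
    return sum(state_pwsa(ledger, r.post) - state_pwsa(ledger, r.pre) for r in refs)


def _next_txn_id(ledger: ServiceAreaLedger, prefix: str) -> str:
    existing = {t.txn_id for t in ledger.journal}
    n = len(ledger.journal) + 1
    while f"{prefix}-{n:04d}" in existing:
        n += 1
    return f"{prefix}-{n:04d}"


def _check_append_order(ledger: ServiceAreaLedger, txn: Transaction) -> None:
    if ledger.journal and txn.sort_key() < ledger.journal[-1].sort_key():
        raise LedgerError(
            f"journal is append-only: {txn.txn_id} at {txn.timestamp} precedes the last entry"
        )


def apply_transaction(ledger: ServiceAreaLedger, txn: Transaction) -> None:
    """Apply one journal entry to the ledger state (parcels and accounts).

    This is the single mutation path: the record_* constructors and
    :func:`replay` both funnel through it, which makes replay exact.
    """
    for ref in txn.parcel_refs:
        if ref.pre is None:
            if ref.parcel_id in ledger.parcels:
                raise LedgerError(f"{txn.txn_id}: created parcel {ref.parcel_id!r} already exists")
            assert ref.post is not None
            ledger.parcels[ref.parcel_id] = Parcel(
                parcel_id=ref.parcel_id,
                ecotype=ref.post.ecotype,
                area=ref.post.area,
                suitability=copy.deepcopy(ref.post.suitability),
                status=ref.post.status,
                terrestrial_class=ref.post.terrestrial_class,
            )
            continue
        parcel = ledger.parcels.get(ref.parcel_id)
        if parcel is None:
            raise LedgerError(f"{txn.txn_id}: references unknown parcel {ref.parcel_id!r}")
        if ref.post is None:
            parcel.status = "retired"
        else:
            parcel.ecotype = ref.post.ecotype
            parcel.area = ref.post.area
            parcel.suitability = copy.deepcopy(ref.post.suitability)
            parcel.status = ref.post.status
            parcel.terrestrial_class = ref.post.terrestrial_class

    if txn.kind == "deposit":
        created = [r.parcel_id for r in txn.parcel_refs if r.pre is None]
        ledger.accounts[txn.txn_id] = DepositAccount(
            txn_id=txn.txn_id,
            full_pwsa=txn.pwsa_delta,
            deposit_date=txn.timestamp,
            maturity_date=txn.maturity_date or txn.timestamp,
            schedule=txn.schedule or ledger.maturation_schedule,
            parcel_ids=created,
        )
    elif txn.kind == "trade":
        for leg in txn.trade_legs or []:
            ledger.accounts[leg.deposit_ref].committed_pwsa += leg.pwsa_used
        if txn.withdrawal_ref:
            ledger.offset_withdrawals.add(txn.withdrawal_ref)
    elif txn.kind == "transfer_out":
        for leg in txn.trade_legs or []:
            ledger.accounts[leg.deposit_ref].committed_pwsa += leg.pwsa_used
    elif txn.kind == "transfer_in":
        ledger.accounts[txn.txn_id] = DepositAccount(
            txn_id=txn.txn_id,
            full_pwsa=float(txn.transfer_pwsa or 0.0),
            deposit_date=txn.timestamp,
            maturity_date=txn.timestamp,
            schedule="step",
            parcel_ids=[],
        )


def _record(ledger: ServiceAreaLedger, txn: Transaction) -> Transaction:
    _check_append_order(ledger, txn)
    apply_transaction(ledger, txn)
    ledger.journal.append(txn)
    return txn


def _tradable_source(ledger: ServiceAreaLedger, parcel_id: str, verb: str) -> Parcel:
    parcel = ledger.parcels.get(parcel_id)
    if parcel is None:
        raise LedgerError(f"cannot {verb} unknown parcel {parcel_id!r}")
    if parcel.status == "reserve":
        raise ReserveRuleError(
            f"parcel {parcel_id!r} is a natural capital reserve and is no longer available for trading"
        )
    if parcel.status == "retired":
        raise RetiredParcelError(f"parcel {parcel_id!r} is retired")
    return parcel


def record_deposit(
    ledger: ServiceAreaLedger,
    created_parcels: Sequence[Parcel],
    converted_from: Optional[Sequence[tuple[str, float]]] = None,
    maturity: Optional[_dt.date] = None,
    on: Optional[_dt.date] = None,
    schedule: Optional[str] = None,
    txn_id: Optional[str] = None,
    cost_note: str = "",
) -> Transaction:
    """Record a habitat deposit: creation or improvement of parcels.

    ``converted_from`` lists ``(parcel_id, hectares)`` sources whose area
    funds the created parcels (e.g. terrestrial land converted to wetland;
    terrestrial sources contribute zero pre-PWSA).  If omitted, each
    created parcel must replace an existing tradable parcel of the same id
    and area (an in-place improvement).  Total created area must equal
    total source area: deposits realise quality/productivity gains, never
    new hectares.

    Opens a :class:`DepositAccount` holding the net gain until maturity.
    Raises on reserve/retired sources and on non-positive net gain.
    """
    on = on or _dt.date.today()
    refs: list[ParcelChange] = []
    pre_pwsa = 0.0
    taken_area = 0.0

    if converted_from:
        for pid, take in converted_from:
            parcel = _tradable_source(ledger, pid, "convert")
            if take <= 0 or take > parcel.area + _TOL:
                raise LedgerError(
                    f"cannot take {take} ha from parcel {pid!r} of {parcel.area} ha"
                )
            pre = ParcelState.of(parcel)
            density = effective_suitability(parcel, ledger.guild_weights) * ledger.ppi(parcel.ecotype)
            pre_pwsa += take * density
            taken_area += take
            if abs(take - parcel.area) <= _TOL:
                refs.append(ParcelChange(pid, pre=pre, post=None))
            else:
                post = ParcelState.of(parcel)
                post.area = parcel.area - take
                refs.append(ParcelChange(pid, pre=pre, post=post))
    else:
        for new in created_parcels:
            parcel = _tradable_source(ledger, new.parcel_id, "improve")
            if abs(parcel.area - new.area) > _TOL:
                raise LedgerError(
                    f"in-place improvement of {new.parcel_id!r} must keep its area "
                    f"({parcel.area} ha, got {new.area})"
                )
            pre_pwsa += state_pwsa(ledger, ParcelState.of(parcel))
            taken_area += parcel.area
            refs.append(ParcelChange(parcel.parcel_id, pre=ParcelState.of(parcel), post=None))

    post_pwsa = 0.0
    created_area = 0.0
    for new in created_parcels:
        if new.parcel_id in ledger.parcels and not any(
            r.parcel_id == new.parcel_id and r.post is None for r in refs
        ):
            raise LedgerError(f"created parcel id {new.parcel_id!r} already exists")
        if new.ecotype not in ledger.ecotypes:
            raise LedgerError(f"created parcel {new.parcel_id!r} has unknown ecotype {new.ecotype!r}")
        state = ParcelState.of(new)
        post_pwsa += state_pwsa(ledger, state)
        created_area += new.area
        new_id = new.parcel_id
        if any(r.parcel_id == new_id for r in refs):
            # improvement re-creates under a derived id so create/retire stay distinct
            new_id = f"{new_id}+imp"
        refs.append(ParcelChange(new_id, pre=None, post=state))

    if abs(created_area - taken_area) > 1e-6:
        raise LedgerError(
            f"deposit does not conserve area: created {created_area} ha from {taken_area} ha"
        )
    delta = post_pwsa - pre_pwsa
    if delta <= _TOL:
        raise NonPositiveGainError(f"deposit yields non-positive net PWSA gain ({delta:.6g})")

    txn = Transaction(
        txn_id=txn_id or _next_txn_id(ledger, "dep"),
        kind="deposit",
        timestamp=on,
        parcel_refs=refs,
        pwsa_delta=delta,
        maturity_date=maturity or on + _dt.timedelta(days=ledger.maturation_days),
        schedule=schedule or ledger.maturation_schedule,
        cost_note=cost_note,
    )
    return _record(ledger, txn)


def maturation_fraction(account: DepositAccount, on: _dt.date) -> float:
    """m(t): the fraction of a deposit's full value accrued by ``on``.

    ``step`` holds the whole value until the maturity date; ``linear``
    ramps from 0 at the deposit date to 1 at maturity.
    """
    if on < account.deposit_date:
        raise LedgerError(
            f"date {on} precedes deposit {account.txn_id} made {account.deposit_date}"
        )
    if account.schedule == "step":
        return 1.0 if on >= account.maturity_date else 0.0
    if account.schedule == "linear":
        span = (account.maturity_date - account.deposit_date).days
        if span <= 0:
            return 1.0
        return min(1.0, (on - account.deposit_date).days / span)
    raise LedgerError(f"unknown maturation schedule {account.schedule!r}")


def available_value(account: DepositAccount, on: _dt.date) -> float:
    """Matured, uncommitted PWSA of a deposit account at a date."""
    return account.full_pwsa * maturation_fraction(account, on) - account.committed_pwsa


def record_withdrawal(
    ledger: ServiceAreaLedger,
    impacts: Sequence[tuple[str, float, ParcelState]],
    on: Optional[_dt.date] = None,
    txn_id: Optional[str] = None,
    cost_note: str = "",
) -> Transaction:
    """Record an unavoidable adverse impact on tradable parcels.

    Each impact is ``(parcel_id, hectares, post_state)``: the taken
    hectares leave their parcel and re-appear as ``post_state`` (e.g. an
    infilled embayment becomes terrestrial land), conserving area.  The
    net PWSA delta must be non-positive; a gain is a deposit, not a
    withdrawal.  Impacting a reserve parcel raises
    :class:`ReserveRuleError`.
    """
    on = on or _dt.date.today()
    tid = txn_id or _next_txn_id(ledger, "wdr")
    refs: list[ParcelChange] = []
    delta = 0.0
    for i, (pid, take, post_state) in enumerate(impacts):
        parcel = _tradable_source(ledger, pid, "withdraw from")
        if take <= 0 or take > parcel.area + _TOL:
            raise LedgerError(f"cannot take {take} ha from parcel {pid!r} of {parcel.area} ha")
        if abs(post_state.area - take) > 1e-6:
            raise LedgerError(
                f"withdrawal does not conserve area: {take} ha taken from {pid!r} "
                f"but post-state holds {post_state.area} ha"
            )
        if post_state.ecotype not in ledger.ecotypes:
            raise LedgerError(f"post-state ecotype {post_state.ecotype!r} unknown")
        pre = ParcelState.of(parcel)
        density = effective_suitability(parcel, ledger.guild_weights) * ledger.ppi(parcel.ecotype)
        delta += state_pwsa(ledger, post_state) - take * density
        if abs(take - parcel.area) <= _TOL:
            refs.append(ParcelChange(pid, pre=pre, post=post_state))
        else:
            remain = ParcelState.of(parcel)
            remain.area = parcel.area - take
            refs.append(ParcelChange(pid, pre=pre, post=remain))
            refs.append(ParcelChange(f"{pid}--{tid}.{i}", pre=None, post=post_state))
    if delta > _TOL:
        raise LedgerError(
            f"impacts yield a PWSA gain ({delta:.6g}); record that as a deposit, not a withdrawal"
        )
    txn = Transaction(
        txn_id=tid,
        kind="withdrawal",
        timestamp=on,
        parcel_refs=refs,
        pwsa_delta=delta,
        cost_note=cost_note,
    )
    return _record(ledger, txn)


def solve_offset(
    loss_pwsa: float, suitability: float, ppi: float, offset_ratio: float = 1.0
) -> float:
    """Deposit area needed to offset a loss: area = r x loss / (S_eff x PPI).

    Inverse of valuation: the returned area, valued at the given
    suitability and PPI, reproduces ``offset_ratio x loss_pwsa`` exactly.
    Raises on zero-productivity deposits (the division is undefined:
    such habitat cannot offset anything).
    """
    if loss_pwsa <= 0:
        raise LedgerError(f"loss must be positive, got {loss_pwsa}")
    if offset_ratio < 1.0:
        raise LedgerError(f"offset ratio must be >= 1, got {offset_ratio}")
    density = suitability * ppi
    if density <= 0:
        raise LedgerError(
            "deposit ecotype has zero productivity (suitability x PPI = 0); it cannot offset a loss"
        )
    return offset_ratio * loss_pwsa / density


@dataclass
class TradeResolution:
    """How a withdrawal was offset: the deposits debited and the net result."""

    withdrawal_ref: str
    legs: list[TradeLeg]
    offset_ratio: float
    net_pwsa: float
    txn_id: str


def execute_trade(
    ledger: ServiceAreaLedger,
    withdrawal_ref: str,
    deposit_refs: Optional[Sequence[str]] = None,
    offset_ratio: Optional[float] = None,
    on: Optional[_dt.date] = None,
    txn_id: Optional[str] = None,
) -> TradeResolution:
    """Offset a recorded withdrawal against matured deposits.

    Deposits are debited FIFO by maturity date (ties broken by txn id)
    until ``r x |loss|`` PWSA is covered; the used portions of the
    deposit parcels are split off and flagged ``reserve`` — traded
    deposits join the natural capital reserves and are no longer
    available.  Raises if the withdrawal is unknown or already offset, or
    if matured uncommitted balance is insufficient (an unmatured step
    deposit counts zero: the hold has not cleared).
    """
    on = on or _dt.date.today()
    r = ledger.offset_ratio_default if offset_ratio is None else float(offset_ratio)
    if r < 1.0:
        raise LedgerError(f"offset ratio must be >= 1, got {r}")

    withdrawal = next(
        (t for t in ledger.journal if t.txn_id == withdrawal_ref and t.kind == "withdrawal"),
        None,
    )
    if withdrawal is None:
        raise LedgerError(f"no recorded withdrawal {withdrawal_ref!r}")
    if withdrawal_ref in ledger.offset_withdrawals:
        raise DoubleOffsetError(f"withdrawal {withdrawal_ref!r} has already been offset")
    loss = -withdrawal.pwsa_delta
    need = r * loss
    if need <= 0:
        raise LedgerError(f"withdrawal {withdrawal_ref!r} carries no loss to offset")

    if deposit_refs is None:
        candidates = list(ledger.accounts.values())
    else:
        missing = [d for d in deposit_refs if d not in ledger.accounts]
        if missing:
            raise LedgerError(f"unknown deposit account(s) {missing}; cross-ledger trades are transfers")
        candidates = [ledger.accounts[d] for d in deposit_refs]
    candidates.sort(key=lambda a: (a.maturity_date, a.txn_id))

    available = sum(
        max(0.0, available_value(a, on)) for a in candidates if on >= a.deposit_date
    )
    if available + _TOL < need:
        raise InsufficientBalanceError(
            f"matured uncommitted balance {available:.6g} PWSA cannot cover "
            f"{need:.6g} PWSA (r={r} x loss {loss:.6g}); unmatured deposits are on hold"
        )

    tid = txn_id or _next_txn_id(ledger, "trd")
    legs: list[TradeLeg] = []
    refs: list[ParcelChange] = []
    remaining = need
    for account in candidates:
        if remaining <= _TOL:
            break
        if on < account.deposit_date:
            continue
        avail = available_value(account, on)
        if avail <= _TOL:
            continue
        take = min(avail, remaining)
        remaining -= take
        area_used = 0.0
        to_place = take
        for pid in account.parcel_ids:
            if to_place <= _TOL:
                break
            parcel = ledger.parcels.get(pid)
            if parcel is None or parcel.status != "tradable":
                continue
            density = effective_suitability(parcel, ledger.guild_weights) * ledger.ppi(parcel.ecotype)
            if density <= 0:
                continue
            parcel_pwsa = parcel.area * density
            use = min(to_place, parcel_pwsa)
            a = use / density
            pre = ParcelState.of(parcel)
            if a < parcel.area - _TOL:
                remain_state = ParcelState.of(parcel)
                remain_state.area = parcel.area - a
                used_state = ParcelState.of(parcel)
                used_state.area = a
                used_state.status = "reserve"
                refs.append(ParcelChange(pid, pre=pre, post=remain_state))
                refs.append(ParcelChange(f"{pid}-r.{tid}", pre=None, post=used_state))
            else:
                held = ParcelState.of(parcel)
                held.status = "reserve"
                refs.append(ParcelChange(pid, pre=pre, post=held))
            area_used += a
            to_place -= use
        legs.append(TradeLeg(deposit_ref=account.txn_id, area_used=area_used, pwsa_used=take))

    used_total = sum(l.pwsa_used for l in legs)
    net = used_total - need
    txn = Transaction(
        txn_id=tid,
        kind="trade",
        timestamp=on,
        parcel_refs=refs,
        pwsa_delta=0.0,
        offset_ratio=r,
        withdrawal_ref=withdrawal_ref,
        trade_legs=legs,
    )
    _record(ledger, txn)
    return TradeResolution(
        withdrawal_ref=withdrawal_ref, legs=legs, offset_ratio=r, net_pwsa=net, txn_id=tid
    )


def reserve_parcel(
    ledger: ServiceAreaLedger,
    parcel_ids: Sequence[str],
    rationale: str = "",
    on: Optional[_dt.date] = None,
    txn_id: Optional[str] = None,
) -> Transaction:
    """Set parcels aside as protected natural capital reserves.

    Reserved parcels keep their full valuation but refuse all subsequent
    trading (conversion deposits, withdrawals, trades).  Reserving an
    already-reserved parcel is an idempotent no-op recorded in the
    journal; reserving a retired parcel is an error.
    """
    on = on or _dt.date.today()
    refs: list[ParcelChange] = []
    for pid in parcel_ids:
        parcel = ledger.parcels.get(pid)
        if parcel is None:
            raise LedgerError(f"cannot reserve unknown parcel {pid!r}")
        if parcel.status == "retired":
            raise RetiredParcelError(f"cannot reserve retired parcel {pid!r}")
        pre = ParcelState.of(parcel)
        post = ParcelState.of(parcel)
        post.status = "reserve"
        refs.append(ParcelChange(pid, pre=pre, post=post))
    txn = Transaction(
        txn_id=txn_id or _next_txn_id(ledger, "rsv"),
        kind="reservation",
        timestamp=on,
        parcel_refs=refs,
        pwsa_delta=0.0,
        justification=rationale,
    )
    return _record(ledger, txn)


def record_transfer(
    from_ledger: ServiceAreaLedger,
    to_ledger: ServiceAreaLedger,
    pwsa: float,
    justification: str,
    on: Optional[_dt.date] = None,
) -> tuple[Transaction, Transaction]:
    """Move matured deposit value between service areas.

    A precautionary, exceptional operation: both paired entries carry a
    warning flag and a mandatory justification.  The source bank is
    debited FIFO; the target gains an immediately-available credit
    account.  Degenerate (<= 0) amounts are rejected.
    """
    on = on or _dt.date.today()
    if pwsa <= 0:
        raise TransferError(f"transfer of {pwsa} PWSA is degenerate")
    if not justification.strip():
        raise TransferError("inter-service-area transfers require a non-empty justification")
    accounts = sorted(from_ledger.accounts.values(), key=lambda a: (a.maturity_date, a.txn_id))
    available = sum(
        max(0.0, available_value(a, on)) for a in accounts if on >= a.deposit_date
    )
    if available + _TOL < pwsa:
        raise InsufficientBalanceError(
            f"source bank holds {available:.6g} matured uncommitted PWSA, cannot transfer {pwsa}"
        )
    legs: list[TradeLeg] = []
    remaining = pwsa
    for account in accounts:
        if remaining <= _TOL:
            break
        if on < account.deposit_date:
            continue
        avail = available_value(account, on)
        if avail <= _TOL:
            continue
        take = min(avail, remaining)
        legs.append(TradeLeg(deposit_ref=account.txn_id, area_used=0.0, pwsa_used=take))
        remaining -= take

    out_id = _next_txn_id(from_ledger, "tfo")
    in_id = _next_txn_id(to_ledger, "tfi")
    txn_out = Transaction(
        txn_id=out_id,
        kind="transfer_out",
        timestamp=on,
        pwsa_delta=0.0,
        transfer_pwsa=pwsa,
        trade_legs=legs,
        counterpart=f"{to_ledger.name}:{in_id}",
        warning=True,
        justification=justification,
    )
    txn_in = Transaction(
        txn_id=in_id,
        kind="transfer_in",
        timestamp=on,
        pwsa_delta=0.0,
        transfer_pwsa=pwsa,
        counterpart=f"{from_ledger.name}:{out_id}",
        warning=True,
        justification=justification,
    )
    _record(from_ledger, txn_out)
    _record(to_ledger, txn_in)
    return txn_out, txn_in


def bank_balance(ledger: ServiceAreaLedger, on: _dt.date) -> float:
    """Total matured, uncommitted deposit PWSA across all accounts."""
    total = 0.0
    for account in ledger.accounts.values():
        if on >= account.deposit_date:
            total += max(0.0, available_value(account, on))
    return total


def rebuild(ledger: ServiceAreaLedger) -> ServiceAreaLedger:
    """Reconstruct the current state by replaying the journal from baseline."""
    fresh = ServiceAreaLedger(
        name=ledger.name,
        ecotypes=dict(ledger.ecotypes),
        guild_weights=copy.deepcopy(ledger.guild_weights),
        parcels=copy.deepcopy(ledger.baseline),
        baseline=copy.deepcopy(ledger.baseline),
        objectives=copy.deepcopy(ledger.objectives),
        boundary_metadata=copy.deepcopy(ledger.boundary_metadata),
        offset_ratio_default=ledger.offset_ratio_default,
        maturation_schedule=ledger.maturation_schedule,
        maturation_days=ledger.maturation_days,
    )
    for txn in ledger.sorted_journal():
        apply_transaction(fresh, txn)
        fresh.journal.append(txn)
    return fresh


def replay(ledger: ServiceAreaLedger) -> Valuation:
    """Valuation after replaying the journal from the baseline inventory.

    Deterministic; equals the valuation of the live inventory because
    both paths apply the same transactions through the same routine.
    """
    fresh = rebuild(ledger)
    return valuate(fresh.parcels.values(), fresh.ecotypes, fresh.guild_weights)


def total_area(ledger: ServiceAreaLedger) -> float:
    """Total hectares over non-retired parcels (aquatic + terrestrial)."""
    return sum(p.area for p in ledger.parcels.values() if p.status != "retired")
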