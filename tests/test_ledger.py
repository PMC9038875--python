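"""Transaction semantics: deposits, maturation, withdrawals, trades, transfers."""

import datetime as dt

import pytest
from hypothesis import given, settings, strategies as st

from habledger import (
    DepositAccount,
    Parcel,
    ParcelState,
    available_value,
    bank_balance,
    execute_trade,
    maturation_fraction,
    record_deposit,
    record_transfer,
    record_withdrawal,
    replay,
    reserve_parcel,
    solve_offset,
    total_area,
    valuate,
)
from habledger.errors import (
    DoubleOffsetError,
    InsufficientBalanceError,
    LedgerError,
    NonPositiveGainError,
    ReserveRuleError,
    RetiredParcelError,
    TransferError,
)
from conftest import small_ledger

D0 = dt.date(2024, 1, 1)
D_MAT = dt.date(2025, 1, 1)
LATER = dt.date(2025, 6, 1)


def _deposit_wetland(ledger, suit=0.75, area=1.0, on=D0, maturity=D_MAT):
    return record_deposit(
        ledger,
        created_parcels=[Parcel("bank-w", "wetland", area, suit)],
        converted_from=[("land-1", area)],
        maturity=maturity,
        on=on,
    )


class TestDeposits:
    def test_land_to_wetland_at_075_gains_1_5_pwsa(self, land_and_bay):
        txn = _deposit_wetland(land_and_bay)
        assert txn.pwsa_delta == pytest.approx(1.50)
        assert land_and_bay.parcels["land-1"].status == "retired"
        assert land_and_bay.accounts[txn.txn_id].full_pwsa == pytest.approx(1.50)

    def test_land_to_wetland_at_unit_suitability_gains_2_0(self, land_and_bay):
        txn = _deposit_wetland(land_and_bay, suit=1.0)
        assert txn.pwsa_delta == pytest.approx(2.0)

    def test_zero_suitability_deposit_is_a_non_positive_gain(self, land_and_bay):
        with pytest.raises(NonPositiveGainError):
            _deposit_wetland(land_and_bay, suit=0.0)

    def test_converting_a_reserve_parcel_is_refused(self, land_and_bay):
        reserve_parcel(land_and_bay, ["land-1"], on=D0)
        with pytest.raises(ReserveRuleError):
            _deposit_wetland(land_and_bay, on=dt.date(2024, 2, 1))

    def test_deposits_conserve_total_area(self, land_and_bay):
        before = total_area(land_and_bay)
        _deposit_wetland(land_and_bay)
        assert total_area(land_and_bay) == pytest.approx(before)

    def test_created_area_must_match_converted_area(self, land_and_bay):
        with pytest.raises(LedgerError, match="conserve area"):
            record_deposit(
                land_and_bay,
                created_parcels=[Parcel("bank-w", "wetland", 2.0, 0.75)],
                converted_from=[("land-1", 1.0)],
                maturity=D_MAT,
                on=D0,
            )

    def test_partial_conversion_leaves_a_remainder_parcel(self):
        ledger = small_ledger([Parcel("land-1", "terrestrial", 5.0, 0.0)])
        record_deposit(
            ledger,
            created_parcels=[Parcel("bank-w", "wetland", 2.0, 0.75)],
            converted_from=[("land-1", 2.0)],
            maturity=D_MAT,
            on=D0,
        )
        assert ledger.parcels["land-1"].area == pytest.approx(3.0)
        assert ledger.parcels["bank-w"].area == pytest.approx(2.0)


class TestMaturation:
    def test_step_schedule_holds_until_the_cheque_clears(self):
        acct = DepositAccount("d", 1.5, D0, D_MAT, schedule="step")
        assert available_value(acct, dt.date(2024, 12, 31)) == 0.0
        assert available_value(acct, D_MAT) == pytest.approx(1.5)

    def test_linear_schedule_is_half_value_at_half_interval(self):
        acct = DepositAccount("d", 1.5, D0, D0 + dt.timedelta(days=200), schedule="linear")
        assert available_value(acct, D0 + dt.timedelta(days=100)) == pytest.approx(0.75)

    def test_matured_deposit_with_committed_portion(self):
        acct = DepositAccount("d", 1.5, D0, D_MAT, schedule="step", committed_pwsa=0.5)
        assert available_value(acct, LATER) == pytest.approx(1.0)

    def test_date_before_deposit_is_an_error(self):
        acct = DepositAccount("d", 1.5, D0, D_MAT)
        with pytest.raises(LedgerError):
            available_value(acct, dt.date(2023, 1, 1))

    def test_fraction_is_monotone_nondecreasing(self):
        acct = DepositAccount("d", 1.0, D0, D_MAT, schedule="linear")
        dates = [D0 + dt.timedelta(days=30 * k) for k in range(16)]
        fracs = [maturation_fraction(acct, d) for d in dates]
        assert fracs == sorted(fracs)
        assert fracs[-1] == 1.0


class TestWithdrawals:
    def test_infilling_moderate_embayment_loses_half_a_unit(self, land_and_bay):
        txn = record_withdrawal(
            land_and_bay,
            impacts=[("bay-1", 1.0, ParcelState("terrestrial", 1.0, 0.0))],
            on=D0,
        )
        assert txn.pwsa_delta == pytest.approx(-0.50)

    def test_unit_suitability_infill_loses_one_unit(self):
        ledger = small_ledger([Parcel("bay-1", "embayment", 1.0, 1.0)])
        txn = record_withdrawal(
            ledger, impacts=[("bay-1", 1.0, ParcelState("terrestrial", 1.0, 0.0))], on=D0
        )
        assert txn.pwsa_delta == pytest.approx(-1.0)

    def test_withdrawal_on_reserve_parcel_is_refused(self, land_and_bay):
        reserve_parcel(land_and_bay, ["bay-1"], on=D0)
        with pytest.raises(ReserveRuleError):
            record_withdrawal(
                land_and_bay,
                impacts=[("bay-1", 1.0, ParcelState("terrestrial", 1.0, 0.0))],
                on=dt.date(2024, 2, 1),
            )

    def test_a_gain_must_be_recorded_as_a_deposit(self, land_and_bay):
        with pytest.raises(LedgerError, match="deposit"):
            record_withdrawal(
                land_and_bay,
                impacts=[("bay-1", 1.0, ParcelState("wetland", 1.0, 1.0))],
                on=D0,
            )

    def test_withdrawals_conserve_total_area(self, land_and_bay):
        before = total_area(land_and_bay)
        record_withdrawal(
            land_and_bay,
            impacts=[("bay-1", 0.4, ParcelState("terrestrial", 0.4, 0.0))],
            on=D0,
        )
        assert total_area(land_and_bay) == pytest.approx(before)
        assert land_and_bay.parcels["bay-1"].area == pytest.approx(0.6)


class TestOffsetSolver:
    @pytest.mark.parametrize(
        "loss, suit, ppi, r, expected",
        [
            (0.50, 0.75, 2.0, 1.0, 1.0 / 3.0),
            (1.00, 1.00, 2.0, 1.0, 0.5),
            (0.50, 0.50, 0.5, 2.0, 4.0),
        ],
    )
    def test_solved_area_matches_hand_arithmetic(self, loss, suit, ppi, r, expected):
        assert solve_offset(loss, suit, ppi, r) == pytest.approx(expected)

    def test_zero_productivity_deposit_cannot_offset(self):
        with pytest.raises(LedgerError, match="zero productivity"):
            solve_offset(0.5, 0.0, 2.0)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        loss=st.floats(1e-6, 1e3),
        suit=st.floats(0.01, 1.0),
        ppi=st.floats(0.01, 5.0),
        r=st.floats(1.0, 5.0),
    )
    def test_solver_inverts_valuation(self, loss, suit, ppi, r):
        area = solve_offset(loss, suit, ppi, r)
        assert area * suit * ppi == pytest.approx(r * loss, rel=1e-9)


class TestTrades:
    def _worked_example(self, ledger):
        deposit = _deposit_wetland(ledger)
        withdrawal = record_withdrawal(
            ledger,
            impacts=[("bay-1", 1.0, ParcelState("terrestrial", 1.0, 0.0))],
            on=dt.date(2025, 2, 1),
        )
        return deposit, withdrawal

    def test_worked_trade_is_net_zero_with_one_third_area(self, land_and_bay):
        deposit, withdrawal = self._worked_example(land_and_bay)
        res = execute_trade(land_and_bay, withdrawal.txn_id, on=dt.date(2025, 3, 1))
        assert res.net_pwsa == pytest.approx(0.0, abs=1e-9)
        (leg,) = res.legs
        assert leg.pwsa_used == pytest.approx(0.50)
        assert leg.area_used == pytest.approx(1.0 / 3.0)
        assert available_value(
            land_and_bay.accounts[deposit.txn_id], dt.date(2025, 3, 2)
        ) == pytest.approx(1.00)

    def test_traded_portion_joins_the_reserves(self, land_and_bay):
        _, withdrawal = self._worked_example(land_and_bay)
        res = execute_trade(land_and_bay, withdrawal.txn_id, on=dt.date(2025, 3, 1))
        reserved = [
            p for p in land_and_bay.parcels.values()
            if p.status == "reserve" and p.ecotype == "wetland"
        ]
        assert len(reserved) == 1
        assert reserved[0].area == pytest.approx(1.0 / 3.0)
        assert land_and_bay.parcels["bank-w"].area == pytest.approx(2.0 / 3.0)

    def test_trade_before_maturity_hits_the_hold_rule(self, land_and_bay):
        _deposit_wetland(land_and_bay, maturity=dt.date(2026, 1, 1))
        withdrawal = record_withdrawal(
            land_and_bay,
            impacts=[("bay-1", 1.0, ParcelState("terrestrial", 1.0, 0.0))],
            on=dt.date(2025, 2, 1),
        )
        with pytest.raises(InsufficientBalanceError, match="hold"):
            execute_trade(land_and_bay, withdrawal.txn_id, on=dt.date(2025, 2, 2))

    def test_double_offsetting_the_same_withdrawal_is_refused(self, land_and_bay):
        _, withdrawal = self._worked_example(land_and_bay)
        execute_trade(land_and_bay, withdrawal.txn_id, on=dt.date(2025, 3, 1))
        with pytest.raises(DoubleOffsetError):
            execute_trade(land_and_bay, withdrawal.txn_id, on=dt.date(2025, 3, 2))

    def test_double_entry_holds_with_an_offset_ratio(self):
        ledger = small_ledger(
            [
                Parcel("land-1", "terrestrial", 4.0, 0.0),
                Parcel("bay-1", "embayment", 1.0, 0.5),
            ]
        )
        _deposit_wetland(ledger, area=1.0)
        withdrawal = record_withdrawal(
            ledger,
            impacts=[("bay-1", 1.0, ParcelState("terrestrial", 1.0, 0.0))],
            on=dt.date(2025, 2, 1),
        )
        res = execute_trade(
            ledger, withdrawal.txn_id, offset_ratio=2.0, on=dt.date(2025, 3, 1)
        )
        assert sum(l.pwsa_used for l in res.legs) == pytest.approx(
            2.0 * 0.50, abs=1e-9
        )

    def test_multi_deposit_trades_debit_fifo_by_maturity(self):
        ledger = small_ledger(
            [
                Parcel("land-1", "terrestrial", 10.0, 0.0),
                Parcel("bay-1", "embayment", 4.0, 1.0),
            ]
        )
        late = record_deposit(
            ledger,
            created_parcels=[Parcel("w-late", "wetland", 1.0, 1.0)],
            converted_from=[("land-1", 1.0)],
            maturity=dt.date(2025, 6, 1),
            on=D0,
        )
        early = record_deposit(
            ledger,
            created_parcels=[Parcel("w-early", "wetland", 1.0, 1.0)],
            converted_from=[("land-1", 1.0)],
            maturity=dt.date(2025, 1, 1),
            on=dt.date(2024, 1, 2),
        )
        withdrawal = record_withdrawal(
            ledger,
            impacts=[("bay-1", 3.0, ParcelState("terrestrial", 3.0, 0.0))],
            on=dt.date(2025, 7, 1),
        )
        res = execute_trade(ledger, withdrawal.txn_id, on=dt.date(2025, 7, 2))
        assert [l.deposit_ref for l in res.legs] == [early.txn_id, late.txn_id]
        assert res.legs[0].pwsa_used == pytest.approx(2.0)  # early fully drained first
        assert res.legs[1].pwsa_used == pytest.approx(1.0)

    def test_trades_conserve_total_area(self, land_and_bay):
        _, withdrawal = self._worked_example(land_and_bay)
        before = total_area(land_and_bay)
        execute_trade(land_and_bay, withdrawal.txn_id, on=dt.date(2025, 3, 1))
        assert total_area(land_and_bay) == pytest.approx(before)


class TestReserves:
    def test_reserving_is_idempotent_and_blocks_later_trading(self, land_and_bay):
        reserve_parcel(land_and_bay, ["bay-1"], on=D0)
        txn = reserve_parcel(land_and_bay, ["bay-1"], on=dt.date(2024, 2, 1))
        assert land_and_bay.parcels["bay-1"].status == "reserve"
        ref = txn.parcel_refs[0]
        assert ref.pre.status == ref.post.status == "reserve"

    def test_reserving_a_retired_parcel_is_an_error(self, land_and_bay):
        _deposit_wetland(land_and_bay)  # retires land-1
        with pytest.raises(RetiredParcelError):
            reserve_parcel(land_and_bay, ["land-1"], on=dt.date(2024, 2, 1))

    def test_reserve_set_only_grows_through_a_journal(self, land_and_bay):
        def reserve_set(ledger):
            return {p.parcel_id for p in ledger.parcels.values() if p.status == "reserve"}

        snapshots = [reserve_set(land_and_bay)]
        _deposit_wetland(land_and_bay)
        snapshots.append(reserve_set(land_and_bay))
        withdrawal = record_withdrawal(
            land_and_bay,
            impacts=[("bay-1", 1.0, ParcelState("terrestrial", 1.0, 0.0))],
            on=dt.date(2025, 2, 1),
        )
        snapshots.append(reserve_set(land_and_bay))
        execute_trade(land_and_bay, withdrawal.txn_id, on=dt.date(2025, 3, 1))
        snapshots.append(reserve_set(land_and_bay))
        reserve_parcel(land_and_bay, ["bank-w"], on=dt.date(2025, 4, 1))
        snapshots.append(reserve_set(land_and_bay))
        for earlier, later in zip(snapshots, snapshots[1:]):
            assert earlier <= later


class TestTransfers:
    def _funded(self):
        ledger = small_ledger([Parcel("land-1", "terrestrial", 2.0, 0.0)])
        record_deposit(
            ledger,
            created_parcels=[Parcel("w", "wetland", 1.0, 0.5)],
            converted_from=[("land-1", 1.0)],
            maturity=D_MAT,
            on=D0,
        )
        return ledger

    def test_degenerate_zero_transfer_is_rejected(self):
        with pytest.raises(TransferError, match="degenerate"):
            record_transfer(self._funded(), small_ledger(), 0.0, "why", on=LATER)

    def test_empty_justification_is_rejected(self):
        with pytest.raises(TransferError, match="justification"):
            record_transfer(self._funded(), small_ledger(), 0.5, "  ", on=LATER)

    def test_value_is_conserved_across_ledgers_and_flagged(self):
        source, target = self._funded(), small_ledger()
        out, tin = record_transfer(source, target, 1.0, "no local offsetting option", on=LATER)
        assert out.warning and tin.warning
        assert out.counterpart.endswith(tin.txn_id)
        assert bank_balance(source, LATER) == pytest.approx(0.0)
        assert bank_balance(target, LATER) == pytest.approx(1.0)

    def test_insufficient_matured_balance_is_refused(self):
        with pytest.raises(InsufficientBalanceError):
            record_transfer(self._funded(), small_ledger(), 5.0, "too much", on=LATER)


class TestReplay:
    def test_empty_journal_reproduces_the_baseline(self, land_and_bay):
        vals = replay(land_and_bay)
        live = valuate(
            land_and_bay.parcels.values(), land_and_bay.ecotypes, land_and_bay.guild_weights
        )
        assert vals.total_pwsa == pytest.approx(live.total_pwsa)

    def test_replay_equals_live_state_and_is_deterministic(self, land_and_bay):
        deposit = _deposit_wetland(land_and_bay)
        withdrawal = record_withdrawal(
            land_and_bay,
            impacts=[("bay-1", 1.0, ParcelState("terrestrial", 1.0, 0.0))],
            on=dt.date(2025, 2, 1),
        )
        execute_trade(land_and_bay, withdrawal.txn_id, on=dt.date(2025, 3, 1))
        live = valuate(
            land_and_bay.parcels.values(), land_and_bay.ecotypes, land_and_bay.guild_weights
        )
        first, second = replay(land_and_bay), replay(land_and_bay)
        assert first.pwsa == second.pwsa
        assert first.total_pwsa == pytest.approx(live.total_pwsa, abs=1e-12)
        assert first.total_area == pytest.approx(live.total_area, abs=1e-12)

    def test_journal_touching_unknown_parcel_errors(self, land_and_bay):
        _deposit_wetland(land_and_bay)
        land_and_bay.journal[0].parcel_refs[0].parcel_id = "ghost"
        with pytest.raises(LedgerError, match="unknown parcel"):
            replay(land_and_bay)
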