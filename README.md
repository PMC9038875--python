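# habledger

An ecological accounting engine for **aquatic habitat banking**: it values
habitat parcels in a common productivity-scaled currency, records the
banking transactions of a bounded planning area (deposits, withdrawals,
offset trades, reservations, inter-area transfers) in an append-only
journal, and renders habitat supply balance sheets.

## Who it is for

Habitat bankers, conservation authorities, and regulators running a
*service area* (an integrated planning area such as an urban lake
nearshore) who must demonstrate no-net-loss — or net-gain — of fish
habitat while development proceeds. The engine gives them double-entry
book-keeping for hectares of habitat instead of dollars.

## The accounting currency

Habitat differs both *within* an ecotype (quality) and *between*
ecotypes (maximum potential productivity). Two scalars compose the
common currency:

- **WSA** (weighted suitable area), the within-ecotype measure:
  `WSA_e = Σ_p A_p × S_p` over parcels *p* of ecotype *e*, with area
  `A_p` in hectares and suitability `S_p ∈ [0, 1]`. Guild-resolved
  suitabilities (thermal guild × life stage) are first collapsed with the
  ecotype's percent weight matrix: `S_eff = Σ_{g,s} (w_{g,s,e}/100) ·
  S_{g,s}`.
- **PWSA** (productivity-weighted suitable area), the between-ecotype
  currency: `PWSA_e = PPI_e × WSA_e`, where the potential productivity
  index (PPI) is the ecotype's relative maximum ongoing productivity.
  Defaults: rivermouth 1.5, wetland 2.0, embayment 1.0, open coast 0.5,
  offshore 0.25, terrestrial 0 (land inside the boundary carries no
  aquatic value but its hectares are tracked).

All trades settle in PWSA units. A development loss of `L` PWSA requires
deposit area `A = r·L / (S_eff · PPI)` at offset ratio `r ≥ 1` — the
inverse of the valuation formula. Deposits mature like held cheques: by
default their value is unavailable until the constructed habitat's
maturity date, and traded deposit portions move permanently into the
natural capital reserves.

## Worked example

The packaged fixture encodes a Toronto-waterfront-style nearshore
planning area (15,670 ha across mainland/island buffers and five aquatic
ecotypes) with a three-entry journal: 1 ha of land converted to wetland
(a deposit), 1 ha of embayment infilled (a withdrawal), and a 1:1 trade.

```python
import datetime as dt
import habledger as hl

ledger = hl.make_toronto_fixture()          # class suitabilities 0.75/0.50/0.25
deposit, withdrawal, trade = ledger.sorted_journal()

print(deposit.pwsa_delta)                   # 1.5   (1 ha x 0.75 x PPI 2.0)
print(withdrawal.pwsa_delta)                # -0.5  (1 ha x 0.50 x PPI 1.0)
print(trade.trade_legs[0].area_used)        # 0.3333...  -> 33.3% of the deposit
print(hl.available_value(ledger.accounts[deposit.txn_id], dt.date(2021, 9, 1)))
# 1.0   (deposit remainder banked for future trades)
```

`habledger demo` prints the full supply statement of the
unit-suitability variant:

```
                           mainland  islands  rivermouth  wetland  embayment  open_coast  offshore  total
Baseline supply PWSA              0        0          45      320        830       7,000       110  8,305
Deposit         PWSA              0        0           0        2          0           0         0      2
Withdrawal      PWSA              0        0           0        0         -1           0         0     -1
Bank remainder  PWSA              0        0           0        1          0           0         0      1
Updated supply  PWSA              0        0          45      322        829       7,000       110  8,306
                Area (ha)       130       80          30      161        829      14,000       440 15,670
```

Reading: the deposit adds 2.0 PWSA of wetland, the infill removes 1.0
PWSA of embayment, the 1:1 trade nets zero, and the bank retains 1.0
PWSA (0.5 ha of wetland) for future offsets. Total area is conserved at
15,670 ha — hectares move between ecotypes, they are never created or
destroyed.

The CLI mirrors the library: `init`, `value`, `deposit`, `withdraw`,
`trade`, `transfer`, `reserve`, `report`, `demo`, operating on a ledger
directory (`config.yaml` + `parcels.csv` + `journal.jsonl`). Domain-rule
violations exit 1; usage errors exit 2.

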