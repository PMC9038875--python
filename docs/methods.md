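# Methods

## Model

A *service area ledger* is a bounded planning area holding an ecotype
table (label → potential productivity index, PPI), an optional guild
weight matrix, a parcel inventory, notional per-ecotype objectives, and
an append-only transaction journal. Six ecotypes are modelled:
rivermouth, wetland, embayment, open coast, offshore, and terrestrial.
Terrestrial land is a first-class ecotype with PPI 0 rather than an
exclusion, so land↔water conversions are ordinary ecotype changes and
total area is conserved under every within-area transaction.

Valuation composes two scalars. Within an ecotype, weighted suitable
area `WSA_e = Σ A_p S_p` measures quality-adjusted hectares; between
ecotypes, `PWSA_e = PPI_e · WSA_e` converts to the common trading
currency ("productivity-weighted hectares": dimensionless multiples of
1 ha at suitability 1 in a PPI-1 ecotype). The key assumption is that
relative habitat suitability is an adequate surrogate for relative
productivity, and that the PPI table captures between-ecotype
productivity ratios; both are inputs, not estimates made here.

### Guild combination

Parcels may carry a single scalar suitability or a map over
(thermal guild × life stage). No canonical combination formula exists
for the latter, so the engine uses the convex combination
`S_eff = Σ (w_{g,s,e}/100) · S_{g,s}` with the ecotype's percent weight
column (columns sum to 100). This preserves the [0, 1] range and reduces
to the identity on uniform maps — the two properties that make `S_eff`
interchangeable with a scalar suitability downstream.

### Quality classes

High / Med / Low reporting bands carry representative suitabilities
0.75 / 0.50 / 0.25. Band edges are the midpoints 0.625 and 0.375
(half-open, High closed at the top). Classes are a reporting
convenience only; full-precision suitabilities drive all accounting.

## Transaction semantics

- **Deposit** — habitat creation or improvement. Pre-PWSA of the source
  footprint (zero for terrestrial) is subtracted from the post-PWSA of
  the created parcels; the net gain must be positive, and created
  hectares must equal converted hectares. Each deposit opens an account
  whose value matures under a schedule: `step` (default; zero value
  until the maturity date — the "hold until the cheque clears" rule) or
  `linear` (ramp from deposit date to maturity). The default maturation
  lag is 1095 days (3 years), a mid-range figure for constructed
  littoral habitat to become ecologically functional; it is
  configurable per ledger and per deposit.
- **Withdrawal** — an unavoidable impact. Taken hectares re-appear in a
  stated post-state (typically terrestrial infill at suitability 0);
  the net delta must be non-positive. Withdrawals may precede trades:
  in dense urban areas deposits-first is the ideal, not the rule, so
  uncovered losses are carried as open liabilities rather than refused.
- **Trade** — debits matured, uncommitted deposit value against one
  withdrawal at offset ratio `r ≥ 1` (default 1; no discounting formula
  is imposed — r is policy input). Deposits are debited FIFO by
  maturity date, tie-broken by transaction id. Partially used deposit
  parcels are split: the used portion becomes a new parcel with status
  `reserve` (traded deposits join the natural capital reserves
  permanently), the remainder stays tradable. Double-entry holds
  exactly: Σ debited PWSA = r × |loss|.
- **Reservation** — flags parcels as protected reserves; idempotent,
  irreversible through the public operations (the reserve set only
  grows), and blocking for all subsequent trading.
- **Transfer** — moves matured value between service areas. Treated as
  exceptional: a non-empty justification is mandatory and both paired
  entries carry a warning flag. The receiving ledger gains an
  immediately-available credit account with no parcels attached.

Every mutation flows through a single `apply_transaction` routine; the
journal replayed from the baseline inventory therefore reproduces the
live state exactly, which is the correctness anchor for persistence and
reporting.

## Balance sheet

Rows: baseline supply, one delta row per transaction kind, bank
remainder (Σ matured − committed over accounts; its area column is the
uncommitted tradable area of the account parcels, scaled by the matured
fraction), and updated supply. Columns: terrestrial classes (labels
such as mainland/islands carried on terrestrial parcels), the aquatic
ecotypes in fixed order, then the total. The sheet verifies that
updated = baseline + Σ deltas per column before returning. Percent-of-
total figures use the grand total including terrestrial. Objective
entries are echoed as given, never re-normalised, even when they do not
sum to their printed total — notional inputs are not "corrected".
Rendering rounds areas to 1 decimal and PWSA to 2; totals are computed
pre-rounding and rounded values never feed back.

## Worked-example fixture

`make_toronto_fixture` encodes a Toronto-nearshore-style planning area:
ecotype areas 30 / 160 / 830 / 14,000 / 440 ha plus 130 + 80 ha of
terrestrial buffer, class fractions High 60/80/50/65/50 %, Med
10/15/40/25/30 %, Low 30/5/10/10/20 % per ecotype, one parcel per
(ecotype × class) — the coarsest inventory realising those fractions
exactly — and a three-entry journal (land→wetland deposit, embayment
infill, 1:1 trade). A `unit_suitability` variant values every parcel at
suitability 1.0, the convention of the supply-sheet presentation. The
two published quirks are resolved rather than reproduced: per-ecotype
PWSA is always computed as `PPI × WSA` even where a printed offshore
cell disagrees with its own WSA, and the infill's hectare is returned
to the mainland column so the 15,670 ha total balances without a
bookkeeping gap.

The quality block reports aquatic ecotypes only: terrestrial land is
*defined* to have zero aquatic suitability, which is not the same claim
as "low-quality aquatic habitat".

## Synthetic generator

`generate_service_area` draws a service area from one
`numpy.random.default_rng(seed)` stream (no global randomness): parcel
areas per ecotype are a Dirichlet(5) split of the requested totals
(concentration 5 gives moderately uneven, realistic parcel sizes),
suitabilities come from either class fractions or a Beta(a, b)
distribution, and a reserve fraction is set aside before trading.
Generated transactions run through the ordinary ledger operations in
deposits → withdrawals → trades order so that holds can clear; an
attempt against a fully reserved inventory raises the same reserve-rule
error a manual attempt would. The generator emulates inventory shape
and transaction mixes, not spatial structure: no geometry, no
adjacency, no correlation between neighbouring parcels, and suitability
draws are i.i.d. Passing tests therefore demonstrate the accounting
engine's behaviour, not calibration against field data.

## Numerical choices

- All arithmetic in double precision; comparisons use absolute
  tolerance 1e-9 (1e-6 for hectare conservation, which tolerates
  accumulated splits).
- Journal order is `(date, txn_id)`; dates are calendar dates (the
  published scheme gives no finer temporal resolution) and the id
  tie-break makes ordering total.
- The offset solver refuses zero-productivity deposits (division
  undefined: such habitat cannot offset anything) and ratios below 1.
- Degenerate transfers (≤ 0 PWSA) and empty justifications are errors,
  not warnings.

## Limitations

Suitabilities and PPIs are exogenous inputs — nothing here estimates
them from habitat variables. Financial costing is a free-text note.
GeoJSON geometry is provenance only; areas are always the `area_ha`
attribute, so no projection/CRS handling exists. Ecological
interactions between parcels (connectivity, edge effects) are outside
the accounting model.
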