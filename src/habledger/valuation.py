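"""Parcel and ecotype valuation: effective suitability, WSA, and PWSA.

Within an ecotype the supply of a set of parcels is the weighted suitable
area, WSA = sum(area_p x S_p); across ecotypes each WSA is scaled by the
ecotype's potential productivity index to the common trading currency,
PWSA = PPI x WSA.  Guild-resolved suitabilities are collapsed to one
effective scalar with the ecotype's percent weight column before entering
the WSA sum.

All arithmetic is at full floating precision; rounding happens only when
reports are rendered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .domain_model import (
    HIGH,
    LOW,
    MED,
    LIFE_STAGES,
    THERMAL_GUILDS,
    EcotypeSpec,
    GuildWeightTable,
    Parcel,
    QualityClass,
)
from .errors import LedgerError, UnknownEcotypeError

#: Band edges between the Low/Med/High reporting classes: midpoints
#: between the representative class suitabilities 0.25, 0.50, 0.75.
QUALITY_BAND_EDGES = (0.375, 0.625)


def effective_suitability(parcel: Parcel, weights: Optional[GuildWeightTable] = None) -> float:
    """Collapse a parcel's suitability to a single scalar in [0, 1].

    Scalar suitabilities pass through unchanged.  A (guild, stage) map is
    combined as the convex combination ``sum (w/100) * S`` using the
    weight column of the parcel's ecotype, which preserves the [0, 1]
    range and reduces to the identity on uniform maps.

    Raises :class:`LedgerError` if a mapped parcel has no weight column
    for its ecotype or its map misses a weighted guild-stage cell.
    """
    suit = parcel.suitability
    if not isinstance(suit, Mapping):
        return float(suit)
    if weights is None or not weights.has_ecotype(parcel.ecotype):
        raise LedgerError(
            f"parcel {parcel.parcel_id!r} carries guild-resolved suitabilities but no "
            f"weight column exists for ecotype {parcel.ecotype!r}"
        )
    column = weights.column(parcel.ecotype)
    total = 0.0
    for key, w in column.items():
        if w == 0:
            continue
        if key not in suit:
            raise LedgerError(
                f"parcel {parcel.parcel_id!r} suitability map lacks guild-stage {key}"
            )
        total += (w / 100.0) * float(suit[key])
    return total


def compute_wsa(
    parcels: Iterable[Parcel], weights: Optional[GuildWeightTable] = None
) -> dict[str, float]:
    """Per-ecotype weighted suitable area over non-retired parcels.

    WSA_e = sum over parcels of ecotype e of area x effective suitability.
    Additive over disjoint parcel sets; retired parcels never re-enter
    valuation totals.
    """
    wsa: dict[str, float] = {}
    for parcel in parcels:
        if parcel.status == "retired":
            continue
        s_eff = effective_suitability(parcel, weights)
        wsa[parcel.ecotype] = wsa.get(parcel.ecotype, 0.0) + parcel.area * s_eff
    return wsa


def compute_pwsa(
    wsa: Mapping[str, float], ecotypes: Mapping[str, EcotypeSpec]
) -> dict[str, float]:
    """Scale per-ecotype WSA by PPI: pwsa_e = ppi_e x wsa_e.

    The total is the plain sum over ecotypes.  Raises
    :class:`UnknownEcotypeError` for a WSA key with no PPI.
    """
    out: dict[str, float] = {}
    for eco, value in wsa.items():
        if eco not in ecotypes:
            raise UnknownEcotypeError(f"no PPI for ecotype {eco!r}")
        out[eco] = ecotypes[eco].ppi * value
    return out


def classify_quality(suitability: float) -> QualityClass:
    """Band a scalar suitability into High / Med / Low.

    Half-open bands split at the midpoints between the representative
    class values: High for s >= 0.625, Med for 0.375 <= s < 0.625, Low
    below.  Classes are reporting conveniences only; full-precision
    suitabilities drive all accounting.
    """
    s = float(suitability)
    if not (0.0 <= s <= 1.0):
        raise ValueError(f"suitability {s} outside [0, 1]")
    low_edge, high_edge = QUALITY_BAND_EDGES
    if s >= high_edge:
        return HIGH
    if s >= low_edge:
        return MED
    return LOW


@dataclass
class QualityDistribution:
    """Hectares per quality class, per ecotype and totalled across ecotypes."""

    per_ecotype: dict[str, dict[str, float]]
    totals: dict[str, float]


def quality_distribution(
    parcels: Iterable[Parcel],
    weights: Optional[GuildWeightTable] = None,
    include_terrestrial: bool = False,
) -> QualityDistribution:
    """Distribute non-retired parcel hectares into High/Med/Low classes.

    Each parcel is assigned wholly to the class of its effective
    suitability, so per-ecotype class hectares sum to the ecotype area.
    Terrestrial parcels are excluded by default: they carry zero aquatic
    suitability by convention, which is not the same as low-quality
    aquatic habitat.
    """
    per_ecotype: dict[str, dict[str, float]] = {}
    totals = {"High": 0.0, "Med": 0.0, "Low": 0.0}
    for parcel in parcels:
        if parcel.status == "retired":
            continue
        if parcel.ecotype == "terrestrial" and not include_terrestrial:
            continue
        label = classify_quality(effective_suitability(parcel, weights)).label
        row = per_ecotype.setdefault(parcel.ecotype, {"High": 0.0, "Med": 0.0, "Low": 0.0})
        row[label] += parcel.area
        totals[label] += parcel.area
    return QualityDistribution(per_ecotype=per_ecotype, totals=totals)


@dataclass
class Valuation:
    """Per-ecotype area/WSA/PWSA rollup with grand totals."""

    area: dict[str, float] = field(default_factory=dict)
    wsa: dict[str, float] = field(default_factory=dict)
    pwsa: dict[str, float] = field(default_factory=dict)

    @property
    def total_area(self) -> float:
        return sum(self.area.values())

    @property
    def total_wsa(self) -> float:
        return sum(self.wsa.values())

    @property
    def total_pwsa(self) -> float:
        return sum(self.pwsa.values())


def valuate(
    parcels: Iterable[Parcel],
    ecotypes: Mapping[str, EcotypeSpec],
    weights: Optional[GuildWeightTable] = None,
) -> Valuation:
    """Full rollup of an inventory: area, WSA and PWSA per ecotype."""
    parcels = list(parcels)
    area: dict[str, float] = {}
    for parcel in parcels:
        if parcel.status == "retired":
            continue
        area[parcel.ecotype] = area.get(parcel.ecotype, 0.0) + parcel.area
    wsa = compute_wsa(parcels, weights)
    pwsa = compute_pwsa(wsa, ecotypes)
    return Valuation(area=area, wsa=wsa, pwsa=pwsa)
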