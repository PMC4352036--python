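"""Grey petrel case-study dataset sizes.

Monthly presence counts (geolocator fixes inside each month's 50% density
contour) and per-month background lattice sizes for the three grey petrel
*Procellaria cinerea* study populations — Antipodes Island (south-west
Pacific), Kerguelen Islands (south-east Indian Ocean) and Marion Island
(south-west Indian Ocean, validation only).  These counts are the worked
inputs for the dataset arithmetic of the withholding design: 20% of
presences per month are withheld for validation, as are 100 of the
background points, leaving ``background - 100`` model absences per month.
"""

from __future__ import annotations

from .datasets import round_half_away
from .tracks import SEASON_MONTHS

#: fixes inside the monthly 50% contour, by calendar month (Oct..Feb)
ANTIPODES_MONTHLY_PRESENCES = {10: 478, 11: 595, 12: 614, 1: 611, 2: 306}
KERGUELEN_MONTHLY_PRESENCES = {10: 133, 11: 248, 12: 296, 1: 271, 2: 158}
MARION_MONTHLY_PRESENCES = {10: 128, 11: 136, 12: 137, 1: 137, 2: 127}

#: background lattice size per month (one point per 100-km cell of the 90% contour)
ANTIPODES_MONTHLY_BACKGROUND = 867
KERGUELEN_MONTHLY_BACKGROUND = 452
MARION_MONTHLY_BACKGROUND = 435

#: backgrounds withheld from each month for validation
BACKGROUND_WITHHELD_PER_MONTH = 100
PRESENCE_WITHHOLD_FRACTION = 0.20

#: combined-model down-weight applied to the larger (Antipodes) population
COMBINED_DOWNWEIGHT = 0.76


def monthly_withheld(presences: dict[int, int],
                     fraction: float = PRESENCE_WITHHOLD_FRACTION) -> dict[int, int]:
    """Presences withheld per month under the rounding rule (half away from zero)."""
    return {m: int(round_half_away(fraction * n)) for m, n in presences.items()}


def total_withheld(presences: dict[int, int],
                   fraction: float = PRESENCE_WITHHOLD_FRACTION) -> int:
    return sum(monthly_withheld(presences, fraction).values())


def model_absences_per_month(background: int,
                             withheld: int = BACKGROUND_WITHHELD_PER_MONTH) -> int:
    """Background points entering the model each month after withholding."""
    if withheld > background:
        raise ValueError("cannot withhold more background points than exist")
    return background - withheld


def season_order(counts: dict[int, int]) -> list[int]:
    """Counts listed in non-breeding season order (Oct..Feb)."""
    return [counts[m] for m in SEASON_MONTHS if m in counts]
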