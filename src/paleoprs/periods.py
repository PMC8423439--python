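"""Broad European time periods and the carbon-date conventions tying them together.

Ages are years BP (before present, standardized to 1950 CE), so an age in
years BCE converts as ``BP = BCE + 1950``. Modern samples carry age 0 by
definition. Period bounds follow the archaeological convention of
overlapping Neolithic/post-Neolithic (and Mesolithic/Neolithic) ranges;
where a sample falls in an overlap zone and carries no explicit label, it
is assigned to the interval whose midpoint is nearest.
"""

from __future__ import annotations

import math

#: Chronological order, oldest first.
PERIOD_ORDER = ["EUP", "LUP", "Mesolithic", "Neolithic", "PostNeolithic", "Modern"]

#: Periods preceding the Neolithic transition (the "pre" side of piecewise fits).
PRE_NEOLITHIC = frozenset({"EUP", "LUP", "Mesolithic"})

#: Neolithic and later (the "post" side); modern samples sit here at age 0.
POST_NEOLITHIC = frozenset({"Neolithic", "PostNeolithic", "Modern"})

#: Radiocarbon "present" is 1950 CE.
BP_OFFSET = 1950


def bce_to_bp(bce: float) -> float:
    """Convert years BCE to years BP (present standardized to 1950)."""
    return bce + BP_OFFSET


#: Default period bounds in years BP, ``(low, high)`` inclusive.
#: EUP: before 25,000 BCE; LUP: 25,000-11,000 BCE; Mesolithic: 11,000-5,500 BCE;
#: Neolithic: 8,500-3,900 BCE; post-Neolithic: 5,000 BCE onward; Modern: age 0.
DEFAULT_BOUNDS_BP: dict[str, tuple[float, float]] = {
    "EUP": (bce_to_bp(25000), math.inf),
    "LUP": (bce_to_bp(11000), bce_to_bp(25000)),
    "Mesolithic": (bce_to_bp(5500), bce_to_bp(11000)),
    "Neolithic": (bce_to_bp(3900), bce_to_bp(8500)),
    "PostNeolithic": (1, bce_to_bp(5000)),
    "Modern": (0, 0),
}


def candidate_periods(age_bp: float, bounds: dict[str, tuple[float, float]] | None = None) -> list[str]:
    """All periods whose (inclusive) bound interval contains ``age_bp``."""
    bounds = DEFAULT_BOUNDS_BP if bounds is None else bounds
    out = []
    for period in PERIOD_ORDER:
        if period not in bounds:
            continue
        lo, hi = bounds[period]
        if period == "EUP":
            # "before 25,000 BCE" is strict; 25,000 BCE exactly belongs to the LUP.
            if age_bp > lo:
                out.append(period)
        elif lo <= age_bp <= hi:
            out.append(period)
    return out


def resolve_period(age_bp: float, bounds: dict[str, tuple[float, float]] | None = None) -> str | None:
    """Assign a period to an unlabeled age; overlap zones go to the nearest midpoint.

    Returns ``None`` when the age falls in no interval.
    """
    bounds = DEFAULT_BOUNDS_BP if bounds is None else bounds
    cands = candidate_periods(age_bp, bounds)
    if not cands:
        return None
    if len(cands) == 1:
        return cands[0]

    def midpoint_distance(period: str) -> float:
        lo, hi = bounds[period]
        if math.isinf(hi):  # open-ended oldest interval: distance to its floor
            return abs(age_bp - lo)
        return abs(age_bp - (lo + hi) / 2.0)

    return min(cands, key=lambda p: (midpoint_distance(p), PERIOD_ORDER.index(p)))
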