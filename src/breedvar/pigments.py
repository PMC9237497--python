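"""Chlorophyll and carotenoid quantification from spectrophotometric
absorbances (Arnon-style equations).

Total chlorophyll (mg per g fresh leaf mass):

    chl = (20.2 * OD645 + 8.02 * OD663) * V / (1000 * W)

Carotenoids (mg per g fresh leaf mass):

    car = (7.6 * OD480 - 1.49 * OD510) * V / (d * 1000 * W)

with V the extract volume (mL), W the leaf tissue mass (g) and d the light
path length (cm, 1.4 by default).  The chlorophyll form carries no path
length, exactly as conventionally printed.  A negative carotenoid bracket
(physically impossible) is clipped to zero with a logged warning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

logger = logging.getLogger(__name__)

DEFAULT_PATH_LENGTH_CM = 1.4


@dataclass(frozen=True)
class PigmentReading:
    """One spectrophotometer reading of a leaf extract."""

    od645: float
    od663: float
    od480: float
    od510: float
    v: float  # extract volume, mL
    w: float  # fresh leaf mass, g
    d: float = DEFAULT_PATH_LENGTH_CM  # light path, cm

    def __post_init__(self) -> None:
        for name in ("od645", "od663", "od480", "od510"):
            val = getattr(self, name)
            if not math.isfinite(val) or val < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {val!r}")
        if not self.v > 0:
            raise ValueError(f"extract volume V must be > 0, got {self.v!r}")
        if not self.w > 0:
            raise ValueError(f"tissue mass W must be > 0, got {self.w!r}")
        if not self.d > 0:
            raise ValueError(f"light path d must be > 0, got {self.d!r}")


def chlorophyll_total(reading: PigmentReading) -> float:
    """Total chlorophyll, mg per g fresh mass.  Linear in V, inverse in W."""
    return (20.2 * reading.od645 + 8.02 * reading.od663) * reading.v / (1000.0 * reading.w)


def carotenoids(reading: PigmentReading) -> float:
    """Carotenoid content, mg per g fresh mass; negative brackets clip to 0."""
    bracket = 7.6 * reading.od480 - 1.49 * reading.od510
    value = bracket * reading.v / (reading.d * 1000.0 * reading.w)
    if value < 0:
        logger.warning(
            "carotenoid estimate %.6g mg/g is negative; clipped to 0", value
        )
        return 0.0
    return value
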