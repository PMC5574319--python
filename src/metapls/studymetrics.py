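"""Edema-corrected infarct-volume percentage.

I% = (Vc - Vi) / Vc * 100, where Vc is the volume of the intact
contralateral hemisphere and Vi the volume of the intact regions of the
ipsilateral hemisphere.  Measuring intact ipsilateral tissue (rather than
infarcted tissue directly) corrects for edema swelling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = ["InfarctMeasurement", "infarct_percentage"]

#: Vi larger than this multiple of Vc is implausible even with edema.
_EDEMA_SANITY_FACTOR = 1.5


@dataclass(frozen=True)
class InfarctMeasurement:
    """Hemisphere volumes in mm^3."""

    v_contralateral: float  # Vc, intact left hemisphere
    v_intact_ipsilateral: float  # Vi, intact regions of the right hemisphere

    def __post_init__(self) -> None:
        if self.v_contralateral <= 0:
            raise ValueError("contralateral volume Vc must be positive")
        if self.v_intact_ipsilateral < 0:
            raise ValueError("intact ipsilateral volume Vi must be non-negative")
        if self.v_intact_ipsilateral > self.v_contralateral * _EDEMA_SANITY_FACTOR:
            warnings.warn(
                f"Vi={self.v_intact_ipsilateral} exceeds {_EDEMA_SANITY_FACTOR} x "
                f"Vc={self.v_contralateral}; check the measurements",
                stacklevel=3,
            )


def infarct_percentage(m: InfarctMeasurement) -> float:
    """Percentage infarct volume, I% = (Vc - Vi) / Vc * 100.

    Negative results (Vi > Vc, possible with measurement noise and edema)
    are returned as-is with a warning rather than clamped.
    """
    pct = (m.v_contralateral - m.v_intact_ipsilateral) / m.v_contralateral * 100.0
    if pct < 0:
        warnings.warn(
            f"negative infarct percentage ({pct:.2f}%): Vi exceeds Vc", stacklevel=2
        )
    return pct
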