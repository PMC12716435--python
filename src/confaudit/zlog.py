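"""Reference-range-based zlog transformation of analyte concentrations.

Clinical laboratory analytes such as CA125 and HE4 span several orders of
magnitude between healthy and pathological samples.  The zlog transform maps
a concentration onto an approximately standard-normal scale using the
log-transformed limits of a healthy-population reference interval, treated
as the 2.5th and 97.5th percentiles:

    z(x) = (ln x - (ln L + ln U) / 2) * 3.92 / (ln U - ln L)

so that z(L) = -1.96, z(U) = +1.96 and the geometric mean of the limits maps
to zero.  When only an upper reference limit is published, the lower limit
is conventionally set to 15% of the upper limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: Span of the central 95% of a standard normal (2 * 1.96).
ZLOG_SPAN = 3.92

#: Default fraction used to derive a lower reference limit from the upper.
LOWER_LIMIT_FRACTION = 0.15


@dataclass(frozen=True)
class ReferenceRange:
    """Healthy-population reference interval for one analyte.

    Parameters
    ----------
    lower : float
        Lower reference limit (2.5th percentile estimate), > 0.
    upper : float
        Upper reference limit (97.5th percentile estimate), > ``lower``.
    analyte : str
        Analyte name, e.g. ``"CA125"``.
    units : str
        Concentration units, e.g. ``"U/mL"``.
    """

    lower: float
    upper: float
    analyte: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.lower < self.upper):
            raise ValueError(
                f"reference range requires 0 < lower < upper, got "
                f"({self.lower}, {self.upper}) for {self.analyte or 'analyte'}"
            )

    @classmethod
    def from_upper(cls, upper: float, analyte: str = "", units: str = "") -> "ReferenceRange":
        """Build a range from an upper limit via the 15% lower-limit rule."""
        return cls(lower_from_upper(upper), upper, analyte, units)

    @property
    def log_center(self) -> float:
        return 0.5 * (math.log(self.lower) + math.log(self.upper))

    @property
    def log_scale(self) -> float:
        return (math.log(self.upper) - math.log(self.lower)) / ZLOG_SPAN


#: CA125 range: upper limit 35 U/mL, lower limit from the 15% rule (5.25).
CA125_RANGE = ReferenceRange(5.25, 35.0, "CA125", "U/mL")
#: HE4 range: upper limit 140 pmol/L, lower limit from the 15% rule (21).
HE4_RANGE = ReferenceRange(21.0, 140.0, "HE4", "pmol/L")


def lower_from_upper(upper: float) -> float:
    """Lower reference limit as 15% of the upper limit.

    Used when no firm guidance exists for an analyte's lower limit:
    35 U/mL -> 5.25 U/mL (CA125); 140 pmol/L -> 21 pmol/L (HE4).
    """
    if upper <= 0:
        raise ValueError(f"upper reference limit must be positive, got {upper}")
    return LOWER_LIMIT_FRACTION * upper


def zlog(x, reference: ReferenceRange):
    """zlog-transform concentration(s) ``x`` under ``reference``.

    Accepts a scalar or array; concentrations must be strictly positive.
    Returns a dimensionless value with z(lower) = -1.96 and z(upper) = 1.96.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ValueError("concentrations must be finite and strictly positive")
    z = (np.log(arr) - reference.log_center) / reference.log_scale
    return float(z) if np.isscalar(x) else z


def inverse_zlog(z, reference: ReferenceRange):
    """Concentration corresponding to zlog value(s) ``z`` under ``reference``.

    Exact inverse of :func:`zlog`: ``inverse_zlog(zlog(x)) == x`` up to
    floating-point round-off.
    """
    arr = np.asarray(z, dtype=float)
    x = np.exp(reference.log_center + arr * reference.log_scale)
    return float(x) if np.isscalar(z) else x
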