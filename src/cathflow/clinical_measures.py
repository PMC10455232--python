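"""Non-trace clinical measurements.

Triplicate ultrasound bladder-scan handling (pre-catheterisation eligibility
and post-catheterisation residual), and dichotomisation of the seven-level
dipstick haematuria reading into the positive/negative marker used as a
microtrauma proxy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .errors import DataError

#: minimum pre-catheterisation volume (mL) required in all three scans
ELIGIBILITY_VOLUME_ML = 150.0

#: dipstick categories read as haematuria-positive
DIPSTICK_POSITIVE = frozenset(
    {
        "haemolysed 25 (1+)",
        "haemolysed 80 (2+)",
        "non-haemolysed 80 (2+)",
        "haemolysed 200 (3+)",
    }
)

#: dipstick categories read as negative
DIPSTICK_NEGATIVE = frozenset(
    {
        "negative",
        "non-haemolysed 10 (+/-)",
        "haemolysed 10 (+/-)",
    }
)


@dataclass(frozen=True)
class ScanSummary:
    """Summary of one triplicate bladder-scan measurement."""

    mean_volume: float       # arithmetic mean of the three scans (mL)
    all_at_or_above_150: bool  # eligibility: every scan >= 150 mL


def summarize_scan(triplet: Sequence[float]) -> ScanSummary:
    """Summarise a triplicate bladder scan.

    The eligibility flag is true only when all three measurements reach the
    150 mL minimum; the aggregate is the arithmetic mean.
    """
    vals = [float(x) for x in triplet]
    if len(vals) != 3:
        raise DataError(f"scan triplet must have exactly 3 values, got {len(vals)}")
    if any(v < 0 for v in vals):
        raise DataError("scan volumes must be non-negative")
    return ScanSummary(
        mean_volume=sum(vals) / 3.0,
        all_at_or_above_150=min(vals) >= ELIGIBILITY_VOLUME_ML,
    )


def classify_dipstick(category: str) -> bool:
    """Dichotomise a dipstick category; True means haematuria-positive."""
    if category in DIPSTICK_POSITIVE:
        return True
    if category in DIPSTICK_NEGATIVE:
        return False
    raise DataError(f"unknown dipstick category {category!r}")
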