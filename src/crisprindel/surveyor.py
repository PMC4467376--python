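"""SURVEYOR nuclease assay quantification.

The assay amplifies the target locus, re-hybridises the products and cuts
heteroduplexes; the fraction of cleaved material read off a gel estimates
the fraction of modified alleles via the standard closed form

    % genes modified = (1 - sqrt(1 - fraction cleaved)) * 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence


@dataclass(frozen=True)
class SurveyorMeasurement:
    """Background-corrected band intensities for one lane.

    ``background`` is subtracted from every band and negative values floor
    at zero.
    """

    parent_intensity: float
    cleaved_intensities: Sequence[float] = field(default_factory=tuple)
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.parent_intensity < 0 or self.background < 0 or any(
                v < 0 for v in self.cleaved_intensities):
            raise ValueError("band intensities must be non-negative")

    @property
    def corrected_parent(self) -> float:
        return max(self.parent_intensity - self.background, 0.0)

    @property
    def corrected_cleaved(self) -> list[float]:
        return [max(v - self.background, 0.0) for v in self.cleaved_intensities]


def fraction_cleaved(m: SurveyorMeasurement) -> float:
    """cleaved / (cleaved + parent), after background subtraction."""
    cleaved = sum(m.corrected_cleaved)
    total = cleaved + m.corrected_parent
    if total <= 0:
        raise ValueError("all bands are zero after background subtraction")
    return cleaved / total


def percent_modified(fc: float) -> float:
    """(1 - sqrt(1 - fc)) * 100 for a cleaved fraction fc in [0, 1].

    The square root accounts for heteroduplex formation: with modified
    allele fraction p, a random re-hybridised duplex is cleavable
    (mismatched) unless both strands are unmodified, so fc = 1 - (1 - p)^2.
    """
    if not 0.0 <= fc <= 1.0:
        raise ValueError(f"fraction cleaved must lie in [0, 1], got {fc}")
    return (1.0 - math.sqrt(1.0 - fc)) * 100.0


def fraction_cleaved_from_percent(percent: float) -> float:
    """Inverse of percent_modified: fc = 1 - (1 - p/100)^2."""
    if not 0.0 <= percent <= 100.0:
        raise ValueError("percent modified must lie in [0, 100]")
    return 1.0 - (1.0 - percent / 100.0) ** 2
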