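"""Deterministic in-vivo bookkeeping helpers.

Small formula-level utilities for tumor measurements: the ellipsoid
volume approximation, the end-of-study survivor rule, and tumor-free
counting.  Inferential statistics (survival curves, rank tests, ANOVA)
are deliberately out of scope; use statsmodels/lifelines directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

log = logging.getLogger(__name__)

SURVIVOR_VOLUME_MM3 = 1000.0


@dataclass
class TumorMeasurement:
    """One caliper measurement (mm); length >= width is enforced by swap."""

    length: float
    width: float
    day: int = 0
    subject_id: str = ""
    clinical_signs: bool = False

    def __post_init__(self) -> None:
        if self.length < 0 or self.width < 0:
            raise ValueError("tumor dimensions must be non-negative")
        if self.width > self.length:
            log.warning(
                "subject %s day %d: width > length, swapping",
                self.subject_id, self.day,
            )
            self.length, self.width = self.width, self.length


def tumor_volume(m: TumorMeasurement) -> float:
    """Ellipsoid approximation: volume = length * width^2 / 2 (mm^3)."""
    return m.length * m.width ** 2 / 2.0


def classify_survivor(
    m: TumorMeasurement,
    volume_cutoff: float = SURVIVOR_VOLUME_MM3,
    require_no_signs: bool = True,
) -> bool:
    """Survivor iff tumor volume < cutoff and (by default) no clinical signs.

    The conservative reading requires both conditions; set
    ``require_no_signs=False`` to count any sub-threshold animal as a
    survivor regardless of clinical signs.
    """
    small = tumor_volume(m) < volume_cutoff
    if require_no_signs:
        return small and not m.clinical_signs
    return small


def tumor_free_fraction(
    measurements: list[TumorMeasurement],
) -> tuple[int, int, float]:
    """Count subjects with zero recorded tumor volume at all timepoints.

    Returns ``(n_free, n_total, fraction)`` over the distinct subjects
    present in the measurement list.
    """
    if not measurements:
        raise ValueError("no measurements given")
    ever_tumor: dict[str, bool] = {}
    for m in measurements:
        ever_tumor.setdefault(m.subject_id, False)
        if tumor_volume(m) > 0:
            ever_tumor[m.subject_id] = True
    n_total = len(ever_tumor)
    n_free = sum(1 for has in ever_tumor.values() if not has)
    return n_free, n_total, n_free / n_total
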