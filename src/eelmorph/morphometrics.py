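"""Vertebrate shape index (VSI) and its component aspect ratios.

VSI summarises axial elongation in one number::

    VSI = L_axis1/L_axis2
        + L_head_in_vertebrae * AR_head
        + N_PCV * AR_PCV
        + N_CV  * AR_CV

where ``L_axis1`` is standard length, ``L_axis2`` the maximum body depth
(or width), the head term expresses head length in vertebral units
weighted by the head's aspect ratio, and the two vertebral terms weight
the precaudal/caudal counts by the mean length-to-height aspect ratio of
three selected centra per region. All terms are dimensionless, so VSI is
invariant under uniform rescaling of the linear measurements.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

from .errors import RecordError
from .types import SpecimenRecord, VertebraMeasurement

_VSI_FIELDS = (
    "L_axis1", "L_axis2", "L_head_in_vertebrae", "AR_head",
    "N_PCV", "AR_PCV", "N_CV", "AR_CV",
)


@dataclass
class VSIResult:
    """Per-taxon VSI with its four summands (ratio, head, precaudal, caudal)."""

    taxon_id: str
    vsi: float
    term_ratio: float
    term_head: float
    term_pcv: float
    term_cv: float


def mean_aspect_ratio(measurements: Sequence[VertebraMeasurement], region: str) -> float:
    """Arithmetic mean of centrum length/height over exactly three
    vertebrae of the requested region.

    The index convention uses three selected centra per region; callers
    choose them (see :func:`select_three`).
    """
    ms = list(measurements)
    if len(ms) != 3:
        raise RecordError(f"mean_aspect_ratio needs exactly 3 vertebrae, got {len(ms)}")
    for m in ms:
        if m.region != region:
            raise RecordError(
                f"{m.taxon_id}: vertebra {m.index} is {m.region}, expected {region}"
            )
        if m.centrum_height == 0:
            raise RecordError(f"{m.taxon_id}: vertebra {m.index} has zero height")
    return sum(m.aspect_ratio for m in ms) / 3.0


def select_three(
    measurements: Sequence[VertebraMeasurement],
    region: str,
    indices: Optional[Sequence[int]] = None,
) -> List[VertebraMeasurement]:
    """Pick the three centra used for a region's mean aspect ratio.

    Default rule: the centra nearest 25%, 50% and 75% of the region's
    ordinal span — a reproducible stand-in for manual selection.
    Explicit ``indices`` override the rule.
    """
    pool = sorted((m for m in measurements if m.region == region), key=lambda m: m.index)
    if indices is not None:
        by_ix = {m.index: m for m in pool}
        missing = [i for i in indices if i not in by_ix]
        if missing:
            raise RecordError(f"requested {region} vertebrae not measured: {missing}")
        chosen = [by_ix[i] for i in indices]
    else:
        if len(pool) < 3:
            raise RecordError(
                f"need >= 3 measured {region} vertebrae, have {len(pool)}"
            )
        n = len(pool)
        picks = []
        used = set()
        for q in (0.25, 0.50, 0.75):
            j = round(q * (n - 1))
            while j in used:  # collide only when n is tiny
                j += 1
            used.add(j)
            picks.append(pool[j])
        chosen = picks
    if len(chosen) != 3:
        raise RecordError(f"selection must yield exactly 3 vertebrae, got {len(chosen)}")
    return chosen


def compute_vsi(rec: SpecimenRecord) -> VSIResult:
    """Evaluate the four-term VSI formula exactly as printed.

    All eight inputs must be present; absent ones are listed in the
    error. Increasing ``N_CV`` by one (``AR_CV`` fixed) increases VSI by
    exactly ``AR_CV`` — the formula is linear in the counts.
    """
    missing = [f for f in _VSI_FIELDS if getattr(rec, f) is None]
    if missing:
        raise RecordError(f"{rec.taxon_id}: VSI inputs absent: {missing}")
    if rec.L_axis2 == 0:
        raise RecordError(f"{rec.taxon_id}: L_axis2 is zero; body-depth ratio undefined")
    term_ratio = rec.L_axis1 / rec.L_axis2
    term_head = rec.L_head_in_vertebrae * rec.AR_head
    term_pcv = rec.N_PCV * rec.AR_PCV
    term_cv = rec.N_CV * rec.AR_CV
    return VSIResult(
        taxon_id=rec.taxon_id,
        vsi=term_ratio + term_head + term_pcv + term_cv,
        term_ratio=term_ratio,
        term_head=term_head,
        term_pcv=term_pcv,
        term_cv=term_cv,
    )
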