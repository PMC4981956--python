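"""Domain types shared by every analysis stage.

All downstream modules consume these types only; no stage re-reads raw
files. Optional measurements are represented as ``None`` ("absent"),
never as 0 — zero is a legal count.

Conventions
-----------
* Lengths are millimetres, ages are Ma before present (larger = older).
* Taxon identifiers are exact-match strings; fossil names are stored
  without the dagger — extinct status is carried by ``status``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Optional

from .errors import RecordError

STATUS_VOCAB = frozenset({"extinct", "extant"})
REGION_VOCAB = frozenset({"precaudal", "caudal"})
ELEMENT_VOCAB = frozenset({"ENB", "EPB", "MT", "POT"})
SIDE_VOCAB = frozenset({"epaxial", "hypaxial"})


def _finite(name: str, value: float, taxon: str) -> None:
    if not math.isfinite(value):
        raise RecordError(f"{taxon}: field '{name}' is not finite ({value!r})")


@dataclass
class SpecimenRecord:
    """One measured individual: linear measurements, vertebral counts and
    the aspect ratios entering the vertebrate shape index (VSI).

    ``L_axis1`` is standard length; ``L_axis2`` the secondary body axis
    (maximum body depth — the axis used for fossils, where width is not
    measurable). ``L_head_in_vertebrae`` is head length expressed in
    vertebral-centrum units and may be fractional. ``N_PCV``/``N_CV`` are
    precaudal/caudal vertebral counts; the ``AR_*`` fields are
    length-to-height aspect ratios of the head and of three selected
    centra per region.
    """

    taxon_id: str
    status: str
    clade: str
    L_axis1: float
    L_axis2: float
    head_length: Optional[float] = None
    L_head_in_vertebrae: Optional[float] = None
    N_PCV: Optional[int] = None
    N_CV: Optional[int] = None
    AR_head: Optional[float] = None
    AR_PCV: Optional[float] = None
    AR_CV: Optional[float] = None

    def __post_init__(self) -> None:
        if self.status not in STATUS_VOCAB:
            raise RecordError(
                f"{self.taxon_id}: status {self.status!r} not in {sorted(STATUS_VOCAB)}"
            )
        for name in ("L_axis1", "L_axis2"):
            v = getattr(self, name)
            _finite(name, v, self.taxon_id)
            if v <= 0:
                raise RecordError(f"{self.taxon_id}: {name} must be > 0, got {v}")
        if self.L_axis1 < self.L_axis2:
            raise RecordError(
                f"{self.taxon_id}: L_axis2 ({self.L_axis2}) exceeds L_axis1 "
                f"({self.L_axis1}); the primary axis must be the longest"
            )
        for name in ("head_length", "L_head_in_vertebrae", "AR_head", "AR_PCV", "AR_CV"):
            v = getattr(self, name)
            if v is not None:
                _finite(name, v, self.taxon_id)
                if v < 0 or (name.startswith("AR") and v == 0):
                    raise RecordError(f"{self.taxon_id}: {name} must be positive, got {v}")
        for name in ("N_PCV", "N_CV"):
            v = getattr(self, name)
            if v is not None and (v < 0 or v != int(v)):
                raise RecordError(f"{self.taxon_id}: {name} must be a count, got {v}")
        if self.N_PCV is not None and self.N_CV is not None:
            if self.N_PCV + self.N_CV < 1:
                raise RecordError(f"{self.taxon_id}: vertebral column must have >= 1 centrum")

    @property
    def n_vertebrae(self) -> Optional[int]:
        """Total vertebral count, absent if either regional count is."""
        if self.N_PCV is None or self.N_CV is None:
            return None
        return self.N_PCV + self.N_CV


@dataclass
class VertebraMeasurement:
    """One vertebral centrum: length and height in mm, with its 1-based
    ordinal position along the column and its region."""

    taxon_id: str
    index: int
    region: str
    centrum_length: float
    centrum_height: float

    def __post_init__(self) -> None:
        if self.region not in REGION_VOCAB:
            raise RecordError(
                f"{self.taxon_id}: region {self.region!r} not in {sorted(REGION_VOCAB)}"
            )
        if self.index < 1 or self.index != int(self.index):
            raise RecordError(f"{self.taxon_id}: vertebra index must be a 1-based ordinal")
        for name in ("centrum_length", "centrum_height"):
            v = getattr(self, name)
            _finite(name, v, self.taxon_id)
            if v <= 0:
                raise RecordError(
                    f"{self.taxon_id}: vertebra {self.index} {name} must be > 0, got {v}"
                )

    @property
    def aspect_ratio(self) -> float:
        return self.centrum_length / self.centrum_height


@dataclass
class TendonObservation:
    """One ossified myoseptal element (epineural ENB, epipleural EPB,
    myorhabdoid MT or posterior-oblique POT) with its vertebral traversal
    count in "N + k" notation and its %TL extent along the body.

    ``k_min``/``k_max`` are the number of centra crossed beyond the
    attachment centrum N; fractional counts (e.g. 2.5) are legal and kept
    exact. ``tl_start``/``tl_end`` are percent of total length from the
    snout.
    """

    taxon_id: str
    element: str
    side: str
    k_min: float
    k_max: float
    tl_start: Optional[float] = None
    tl_end: Optional[float] = None
    element_length: Optional[float] = None

    def __post_init__(self) -> None:
        if self.element not in ELEMENT_VOCAB:
            raise RecordError(
                f"{self.taxon_id}: element {self.element!r} not in {sorted(ELEMENT_VOCAB)}"
            )
        if self.side not in SIDE_VOCAB:
            raise RecordError(
                f"{self.taxon_id}: side {self.side!r} not in {sorted(SIDE_VOCAB)}"
            )
        for name in ("k_min", "k_max"):
            _finite(name, getattr(self, name), self.taxon_id)
        if self.k_min < 0:
            raise RecordError(f"{self.taxon_id}: k_min must be >= 0, got {self.k_min}")
        if self.k_max < self.k_min:
            raise RecordError(
                f"{self.taxon_id}: k_max ({self.k_max}) < k_min ({self.k_min})"
            )
        if (self.tl_start is None) != (self.tl_end is None):
            raise RecordError(f"{self.taxon_id}: tl_start and tl_end must come together")
        if self.tl_start is not None:
            if not (0 <= self.tl_start <= self.tl_end <= 100):
                raise RecordError(
                    f"{self.taxon_id}: %TL extent [{self.tl_start}, {self.tl_end}] "
                    "must satisfy 0 <= start <= end <= 100"
                )
        if self.element_length is not None and self.element_length <= 0:
            raise RecordError(f"{self.taxon_id}: element_length must be > 0")


@dataclass
class CalibrationConstraint:
    """An age constraint on the most recent common ancestor of a tip set.

    ``kind`` is ``fixed`` (the node takes exactly this age) or
    ``minimum`` (the node is at least this old; the oldest descendant
    occurrence can push it older).
    """

    mrca_of: frozenset = field(default_factory=frozenset)
    age: float = 0.0
    kind: str = "fixed"

    def __post_init__(self) -> None:
        self.mrca_of = frozenset(self.mrca_of)
        if not self.mrca_of:
            raise RecordError("calibration constraint with empty tip set")
        if self.age <= 0 or not math.isfinite(self.age):
            raise RecordError(f"constraint on {sorted(self.mrca_of)}: age must be > 0 Ma")
        if self.kind not in ("fixed", "minimum"):
            raise RecordError(f"constraint kind {self.kind!r} must be 'fixed' or 'minimum'")


SPECIMEN_COLUMNS = [f.name for f in fields(SpecimenRecord)]
VERTEBRA_COLUMNS = [f.name for f in fields(VertebraMeasurement)]
TENDON_COLUMNS = [f.name for f in fields(TendonObservation)]
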