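"""Lateral-tendon length estimation from ossified myoseptal bones.

In fossil eels the epineural (ENB) and epipleural (EPB) bones record the
attachment line of each myoseptum on the vertebral axis. If the bone
attaches on centrum N and crosses k further centra ("N + k" notation),
the attachment line spans k + 1 vertebrae; the lateral tendon — and
hence the myoseptum — extends one additional segment anteriorly (the
anterior cones, calibrated on extant *Anguilla*), so its length is
k + 2 vertebral units. Fractional traversal counts are carried exactly.

Myorhabdoid (MT) and posterior-oblique (POT) tendons mark body position
(%TL) but do not define the lateral tendon and are rejected by the
estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

from .errors import RecordError
from .types import TendonObservation


@dataclass
class TendonLengthEstimate:
    """Lateral-tendon length for one taxon/side.

    ``attachment_span_vertebrae`` = k + 1 (centrum N plus k crossed);
    ``tendon_length_vertebrae`` = k + 2 (one extra segment for the
    anterior cones). ``k_lower_bound_length`` reports the estimate from
    ``k_min`` when the observation is a range. ``inferred`` marks an
    estimate mirrored from the opposite side.
    """

    taxon_id: str
    side: str
    attachment_span_vertebrae: float
    tendon_length_vertebrae: float
    k_lower_bound_length: Optional[float] = None
    tendon_length_fraction_tl: Optional[float] = None
    inferred: bool = False


def lateral_tendon_length(obs: TendonObservation) -> TendonLengthEstimate:
    """Estimate lateral-tendon length (vertebral units) from an ENB/EPB
    traversal count.

    When the count is a range ("N + 1/2"), the upper bound ``k_max`` is
    the estimator — consistent with the worked fossil totals — and the
    lower-bound length is reported alongside.
    """
    if obs.element not in ("ENB", "EPB"):
        raise RecordError(
            f"{obs.taxon_id}: element {obs.element} does not define the lateral "
            "tendon; only ENB/EPB traversal counts are usable"
        )
    if obs.k_max < 0:
        raise RecordError(f"{obs.taxon_id}: negative traversal count {obs.k_max}")
    k = obs.k_max
    return TendonLengthEstimate(
        taxon_id=obs.taxon_id,
        side=obs.side,
        attachment_span_vertebrae=k + 1.0,
        tendon_length_vertebrae=k + 2.0,
        k_lower_bound_length=(obs.k_min + 2.0) if obs.k_min != obs.k_max else None,
    )


def mirror_missing_side(
    estimates: Sequence[TendonLengthEstimate],
) -> List[TendonLengthEstimate]:
    """Fill a taxon's unpreserved side by mirroring the other, flagged
    ``inferred`` — the musculotendinous system is epaxially/hypaxially
    symmetrical."""
    by_taxon: Dict[str, Dict[str, TendonLengthEstimate]] = {}
    for e in estimates:
        by_taxon.setdefault(e.taxon_id, {})[e.side] = e
    out = list(estimates)
    for taxon, sides in by_taxon.items():
        for missing, present in (("epaxial", "hypaxial"), ("hypaxial", "epaxial")):
            if missing not in sides and present in sides:
                out.append(replace(sides[present], side=missing, inferred=True))
    return out


def tendon_length_fraction(
    est: TendonLengthEstimate,
    vertebra_lengths: Sequence[float],
    total_length: float,
    at_vertebra: int,
) -> float:
    """Tendon length as a fraction of total body length.

    Sums the centrum lengths spanned starting at ``at_vertebra``
    (1-based into ``vertebra_lengths``); a fractional final centrum is
    pro-rated linearly. Homogeneous of degree 0: rescaling all lengths
    leaves the fraction unchanged.
    """
    if total_length <= 0:
        raise RecordError(f"{est.taxon_id}: total_length must be > 0")
    span = est.tendon_length_vertebrae
    n_full = int(span)
    frac = span - n_full
    first = at_vertebra - 1
    last_needed = first + n_full + (1 if frac > 0 else 0)
    if first < 0 or last_needed > len(vertebra_lengths):
        raise RecordError(
            f"{est.taxon_id}: tendon span of {span} vertebrae from ordinal "
            f"{at_vertebra} exceeds the {len(vertebra_lengths)} measured centra"
        )
    length = sum(vertebra_lengths[first : first + n_full])
    if frac > 0:
        length += frac * vertebra_lengths[first + n_full]
    return length / total_length


def percent_tl(position_mm: float, total_length: float) -> float:
    """Axial position as percent of total length from the snout."""
    if total_length <= 0:
        raise RecordError("total_length must be > 0")
    if position_mm < 0 or position_mm > total_length:
        raise RecordError(
            f"position {position_mm} mm outside body [0, {total_length}] mm"
        )
    return 100.0 * position_mm / total_length


def vertebra_positions(
    head_length: float, centrum_lengths: Sequence[float]
) -> List[float]:
    """Snout distance (mm) of each centrum's posterior margin: head
    length plus cumulative centrum lengths. Strictly increasing."""
    out = []
    pos = head_length
    for cl in centrum_lengths:
        if cl <= 0:
            raise RecordError("centrum lengths must be > 0")
        pos += cl
        out.append(pos)
    return out
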