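"""Footprint mapping to a common reference numbering and overlap metrics.

Footprints measured on different (homologous) receptors are compared by
transferring per-residue buried areas through a pairwise sequence
alignment onto one reference numbering, then summing the per-position
minimum of the two area profiles:

    overlap = sum_p min(area_A(p), area_B(p))

This residue-level convention is used (rather than atom-level surface
intersection after superposition) because the two footprints live on
non-identical receptors where atom correspondence is undefined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .interface import FootprintResult
from .superpose import _align_pair

__all__ = [
    "MappedFootprint",
    "OverlapResult",
    "MappingError",
    "map_footprint",
    "footprint_overlap",
    "occlusion_check",
]


class MappingError(ValueError):
    """A footprint residue cannot be resolved to a sequence position."""


@dataclass
class MappedFootprint:
    """Per-position buried areas expressed in a reference sequence numbering."""

    per_residue_buried: dict[int, float]  # 1-based reference position -> Å²
    provenance: str
    reference_length: int
    unmapped: list[int] = field(default_factory=list)  # source positions lost to gaps

    def __post_init__(self) -> None:
        for pos, area in self.per_residue_buried.items():
            if not (1 <= pos <= self.reference_length):
                raise MappingError(f"position {pos} outside reference length {self.reference_length}")
            if area < 0:
                raise MappingError(f"negative buried area at position {pos}")

    @property
    def total(self) -> float:
        return float(sum(self.per_residue_buried.values()))


@dataclass
class OverlapResult:
    overlap_area: float
    shared_positions: set[int]
    per_position_overlap: dict[int, float]


def map_footprint(
    footprint: FootprintResult,
    source_seq: str,
    reference_seq: str,
    alignment: list[tuple[int, int]] | None = None,
    provenance: str = "",
) -> MappedFootprint:
    """Transfer a footprint onto reference numbering through an alignment.

    Footprint residue seq_ids are interpreted as 1-based positions in
    ``source_seq`` (mature numbering); an inconsistent residue identity or
    out-of-range seq_id raises :class:`MappingError` listing the residues.
    The ``alignment`` is (source_index, reference_index) 0-based pairs; by
    default a global BLOSUM62 alignment (gap open 10 / extend 0.5) is
    computed.  Source positions facing a reference gap are dropped and
    reported in ``unmapped``.
    """
    from .superpose import THREE_TO_ONE

    if alignment is None:
        alignment = _align_pair(source_seq, reference_seq)
    src_to_ref = {i: j for i, j in alignment}

    bad: list[str] = []
    source_areas: dict[int, float] = {}
    for (chain, seq_id, icode), area in footprint.per_residue_buried.items():
        if area <= 0.0:
            continue
        if icode or not (1 <= seq_id <= len(source_seq)):
            bad.append(f"{chain}/{seq_id}{icode}")
            continue
        name3 = footprint.residue_names.get((chain, seq_id, icode), "")
        letter = THREE_TO_ONE.get(name3)
        if letter is not None and source_seq[seq_id - 1] != letter:
            bad.append(f"{chain}/{name3}{seq_id}!={source_seq[seq_id - 1]}")
            continue
        source_areas[seq_id] = source_areas.get(seq_id, 0.0) + area
    if bad:
        raise MappingError(f"footprint residues unresolvable in source sequence: {bad}")

    mapped: dict[int, float] = {}
    unmapped: list[int] = []
    for pos, area in sorted(source_areas.items()):
        j = src_to_ref.get(pos - 1)
        if j is None:
            unmapped.append(pos)
        else:
            mapped[j + 1] = mapped.get(j + 1, 0.0) + area
    return MappedFootprint(
        per_residue_buried=mapped,
        provenance=provenance,
        reference_length=len(reference_seq),
        unmapped=unmapped,
    )


def footprint_overlap(a: MappedFootprint, b: MappedFootprint) -> OverlapResult:
    """Per-position min-area overlap of two footprints on one reference."""
    if a.reference_length != b.reference_length:
        raise MappingError(
            f"footprints use different reference lengths: {a.reference_length} vs {b.reference_length}"
        )
    shared = set(a.per_residue_buried) & set(b.per_residue_buried)
    per_pos = {p: min(a.per_residue_buried[p], b.per_residue_buried[p]) for p in shared}
    return OverlapResult(
        overlap_area=float(sum(per_pos.values())),
        shared_positions=shared,
        per_position_overlap=per_pos,
    )


def occlusion_check(epitope: MappedFootprint, occluder_footprint: MappedFootprint) -> float:
    """Fraction of the epitope's buried area covered by an occluding footprint."""
    total = epitope.total
    if total <= 0.0:
        raise MappingError("epitope has zero area; occlusion fraction undefined")
    return footprint_overlap(epitope, occluder_footprint).overlap_area / total
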