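"""KIR receptor alignments, population variants and epitope intersection.

The receptor family of interest (killer immunoglobulin-like receptors,
KIR2D class) is polymorphic; this module expresses variants catalogued on
any family member in the numbering of a chosen reference receptor
(conventionally KIR2DL3, whose mature numbering the structural residue
labels follow) by walking the columns of a multiple sequence alignment,
then intersects them with a structural epitope footprint.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import AlignIO

from .interface import Contact, FootprintResult

__all__ = [
    "MSA",
    "VariantRecord",
    "MSAError",
    "ReferenceMismatchError",
    "read_msa",
    "write_msa",
    "read_variant_table",
    "to_reference_numbering",
    "intersect_epitope",
]

_AA = set("ACDEFGHIKLMNPQRSTVWYX")
_GAP = "-"


class MSAError(ValueError):
    """Malformed alignment (ragged rows, bad alphabet, unknown record)."""


class ReferenceMismatchError(MSAError):
    """A variant's stated reference amino acid disagrees with the MSA."""


@dataclass
class MSA:
    records: list[tuple[str, str]]  # (id, aligned sequence with gaps)

    def __post_init__(self) -> None:
        if not self.records:
            raise MSAError("alignment has no records")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise MSAError(f"ragged alignment: row lengths {sorted(lengths)}")
        for rid, seq in self.records:
            bad = set(seq.upper()) - _AA - {_GAP}
            if bad:
                raise MSAError(f"record {rid}: unexpected symbols {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    def sequence(self, record_id: str) -> str:
        for rid, seq in self.records:
            if rid == record_id:
                return seq.upper()
        raise MSAError(f"record {record_id!r} not in alignment "
                       f"(has {[rid for rid, _ in self.records]})")

    def ungapped(self, record_id: str) -> str:
        return self.sequence(record_id).replace(_GAP, "")

    def position_to_column(self, record_id: str, position: int) -> int:
        """1-based ungapped position -> 0-based alignment column."""
        seq = self.sequence(record_id)
        count = 0
        for col, ch in enumerate(seq):
            if ch != _GAP:
                count += 1
                if count == position:
                    return col
        raise MSAError(f"{record_id}: position {position} beyond sequence length {count}")

    def column_to_position(self, record_id: str, column: int) -> int | None:
        """0-based column -> 1-based ungapped position, or None at a gap."""
        seq = self.sequence(record_id)
        if seq[column] == _GAP:
            return None
        return len(seq[: column + 1].replace(_GAP, ""))


@dataclass(frozen=True)
class VariantRecord:
    receptor: str
    position: int  # the receptor's own mature numbering, 1-based
    ref_aa: str
    alt_aa: str
    rs_id: str = ""
    frequency: float | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"variant position must be >= 1, got {self.position}")
        if self.ref_aa == self.alt_aa:
            raise ValueError(f"{self.receptor} {self.ref_aa}{self.position}{self.alt_aa}: ref == alt")
        if self.frequency is not None and not (0.0 <= self.frequency <= 1.0):
            raise ValueError(f"frequency {self.frequency} outside [0, 1]")

    @property
    def label(self) -> str:
        return f"{self.receptor} {self.ref_aa}{self.position}{self.alt_aa}"


def read_msa(path: str) -> MSA:
    """Read an aligned FASTA; ragged alignments are rejected, ids preserved."""
    try:
        aln = AlignIO.read(str(path), "fasta")
    except ValueError as exc:
        raise MSAError(f"cannot read alignment {path}: {exc}") from exc
    return MSA(records=[(rec.id, str(rec.seq).upper()) for rec in aln])


def write_msa(msa: MSA, path: str) -> None:
    with open(path, "w") as fh:
        for rid, seq in msa.records:
            fh.write(f">{rid}\n{seq}\n")


def read_variant_table(path: str) -> list[VariantRecord]:
    """CSV with columns receptor,position,ref,alt,rs_id,frequency."""
    df = pd.read_csv(path, dtype={"rs_id": str})
    out = []
    for row in df.itertuples(index=False):
        freq = getattr(row, "frequency", None)
        out.append(
            VariantRecord(
                receptor=str(row.receptor),
                position=int(row.position),
                ref_aa=str(row.ref).upper(),
                alt_aa=str(row.alt).upper(),
                rs_id="" if pd.isna(getattr(row, "rs_id", "")) else str(row.rs_id),
                frequency=None if freq is None or pd.isna(freq) else float(freq),
            )
        )
    return out


def to_reference_numbering(variant: VariantRecord, msa: MSA, reference_id: str) -> int | None:
    """Express a variant position in the reference receptor's numbering.

    The variant's stated reference amino acid is checked against the
    receptor's own sequence in the MSA (guards stale numbering); positions
    whose alignment column is a gap in the reference return ``None``.
    """
    own = msa.ungapped(variant.receptor)
    if variant.position > len(own):
        raise MSAError(
            f"{variant.label}: position beyond {variant.receptor} length {len(own)}"
        )
    found = own[variant.position - 1]
    if found != variant.ref_aa:
        raise ReferenceMismatchError(
            f"{variant.label}: {variant.receptor} has {found} at position "
            f"{variant.position}, expected {variant.ref_aa}"
        )
    col = msa.position_to_column(variant.receptor, variant.position)
    return msa.column_to_position(reference_id, col)


def intersect_epitope(
    variants: list[VariantRecord],
    msa: MSA,
    footprint: FootprintResult,
    contacts: list[Contact] | None = None,
    reference_id: str = "KIR2DL3",
) -> pd.DataFrame:
    """One row per variant: reference position, epitope membership, contacts.

    The footprint must already be expressed in the reference receptor's
    numbering (its residue seq_ids are the mature reference positions).
    ``in_epitope`` is buried_area >= the footprint's epitope threshold.
    """
    buried_by_pos: dict[int, float] = {}
    for (_, seq_id, _), area in footprint.per_residue_buried.items():
        buried_by_pos[seq_id] = buried_by_pos.get(seq_id, 0.0) + area
    kinds_by_pos: dict[int, set[str]] = {}
    for c in contacts or []:
        kinds_by_pos.setdefault(c.partner_b.seq_id, set()).add(c.kind)

    rows = []
    for v in variants:
        ref_pos = to_reference_numbering(v, msa, reference_id)
        buried = 0.0 if ref_pos is None else buried_by_pos.get(ref_pos, 0.0)
        rows.append(
            {
                "variant": v.label,
                "receptor": v.receptor,
                "rs_id": v.rs_id,
                "frequency": v.frequency,
                "reference_position": ref_pos,
                "mapped": ref_pos is not None,
                "buried_area": round(buried, 3),
                "in_epitope": buried >= footprint.epitope_threshold,
                "contact_kinds": ",".join(sorted(kinds_by_pos.get(ref_pos, set()))) if ref_pos else "",
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["reference_position", "variant"], na_position="last", kind="mergesort"
    ).reset_index(drop=True)
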