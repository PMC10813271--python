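"""Orthogonal evidence helpers: alignment-column conservation and qPCR fold change.

Cross-species conservation of the mutated residue and transcript-level
expression changes are the two desk-computable lines of evidence this
module covers.  Conservation is exact-identity based: the claim being
tested is that the reference residue is literally preserved across
species, not merely biochemically similar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from Bio import AlignIO

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY") | {"-", "X"}


@dataclass(frozen=True)
class AlignmentColumn:
    """One column of a protein multiple alignment, with a designated reference row."""

    residues: tuple[str, ...]
    reference_index: int = 0

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("alignment column is empty")
        bad = [r for r in self.residues if r not in AA_ALPHABET]
        if bad:
            raise ValueError(f"invalid residue codes {bad}")
        if not 0 <= self.reference_index < len(self.residues):
            raise ValueError(f"reference index {self.reference_index} out of range")


def column_conservation(col: AlignmentColumn) -> float:
    """Fraction of non-gap rows matching the reference residue.

    Gap rows are excluded from the denominator: a deletion carries no
    information about the residue's identity.  A gap at the reference row
    is an error.
    """
    ref = col.residues[col.reference_index]
    if ref == "-":
        raise ValueError("reference residue is a gap")
    non_gap = [r for r in col.residues if r != "-"]
    return sum(r == ref for r in non_gap) / len(non_gap)


def is_invariant(col: AlignmentColumn) -> bool:
    return column_conservation(col) == 1.0


def conservation_from_fasta(
    path, column: int, reference_id: str | None = None
) -> float:
    """Conservation of a 1-based alignment column read from an aligned FASTA.

    ``reference_id`` picks the reference row by sequence id (default:
    first row).
    """
    aln = AlignIO.read(str(path), "fasta")
    if not 1 <= column <= aln.get_alignment_length():
        raise ValueError(f"column {column} outside alignment of length {aln.get_alignment_length()}")
    residues = tuple(str(rec.seq[column - 1]).upper() for rec in aln)
    ref_index = 0
    if reference_id is not None:
        ids = [rec.id for rec in aln]
        if reference_id not in ids:
            raise ValueError(f"reference id {reference_id!r} not in alignment")
        ref_index = ids.index(reference_id)
    return column_conservation(AlignmentColumn(residues, ref_index))


def ddct_fold_change(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression fold change by the 2^-ddCT method.

    Cycle thresholds of the target gene are normalized against a
    reference gene within each condition, and the case is expressed
    relative to the control: ddCT = (CT_target,case - CT_ref,case)
    - (CT_target,ctrl - CT_ref,ctrl); fold change = 2^-ddCT.
    """
    values = (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl)
    for v in values:
        if not math.isfinite(v) or v <= 0:
            raise ValueError(f"CT values must be finite positive numbers, got {v}")
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return 2.0 ** (-ddct)


def ddct_from_table(path) -> list[tuple[str, float]]:
    """Fold changes from a TSV with columns: label, CT_target_case, CT_ref_case, CT_target_ctrl, CT_ref_ctrl."""
    out = []
    lines = Path(path).read_text().splitlines()
    start = 1 if lines and lines[0].lower().startswith("label") else 0
    for line in lines[start:]:
        if not line.strip():
            continue
        label, *cts = line.split("\t")
        if len(cts) != 4:
            raise ValueError(f"expected 4 CT columns for {label!r}, got {len(cts)}")
        out.append((label, ddct_fold_change(*map(float, cts))))
    return out
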