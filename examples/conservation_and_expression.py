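"""Orthogonal evidence: residue conservation and qPCR fold change.

Cross-species identity of the mutated residue and transcript-level
expression fold changes (2^-ddCT) are the two quick desk checks applied
to a prioritized candidate.  The alignment column below is synthetic:
eight placeholder species, all aspartate at the queried position.
"""

from famprio import AlignmentColumn, column_conservation, ddct_fold_change, is_invariant

# synthetic eight-species column at the mutated residue (aspartate, D)
column = AlignmentColumn(tuple("D" * 8))
print(f"conservation across 8 species : {column_conservation(column):.2f}")
print(f"residue invariant             : {is_invariant(column)}")

# a partially conserved column for contrast (6 of 8 aspartate)
mixed = AlignmentColumn(tuple("DDDDEEDD"))
print(f"partially conserved column    : {column_conservation(mixed):.2f}")

# qPCR: knockdown sample vs control, normalized to a reference gene
fold = ddct_fold_change(
    ct_target_case=26.0,  # target gene, knockdown cells
    ct_ref_case=18.0,     # reference gene, knockdown cells
    ct_target_ctrl=24.0,  # target gene, control cells
    ct_ref_ctrl=18.0,     # reference gene, control cells
)
print(f"relative expression (2^-ddCT) : {fold}  (i.e. {fold:.0%} of control)")
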