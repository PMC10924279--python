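"""Project a read alignment from founder coordinates to the reference.

A founder carrying a 2-base insertion and a 1-base deletion is aligned
to the reference in a toy MSA; a read aligned end-to-end to the founder
(CIGAR 8M) is rewritten into reference coordinates, turning the founder
insertion into read-insertion ops and the founder deletion into a
read-deletion op.
"""

from panproject.msa import ReferenceGuidedMSA
from panproject.projection import build_projection_index, project_alignment
from panproject.records import AlignmentRecord, cigar_to_string

#           ref: ACGT--ACGTA
#       founder: ACGTTTAC-TA    (TT inserted after position 3; G deleted)
msa = ReferenceGuidedMSA(
    reference_name="ref",
    rows={"ref": "ACGT--ACGTA", "founder-1": "ACGTTTAC-TA"},
)
index = build_projection_index(msa, "founder-1")

read = AlignmentRecord(
    read_id="r1", target_name="founder-1", leftmost=2,
    cigar=[("M", 8)], seq="GTTTACTA", mapq=42,
)
projected = project_alignment(read, index, reference="ACGTACGTA")
print(f"founder placement : pos {read.leftmost}, CIGAR {cigar_to_string(read.cigar)}")
print(f"reference placement: pos {projected.leftmost}, "
      f"CIGAR {cigar_to_string(projected.cigar)}")
print(f"NM={projected.tags['NM']} MD={projected.tags['MD']}")
# 2M2I2M1D2M: the two inserted founder bases become read insertions (2I)
# and the founder's missing G becomes a deletion (1D) against the reference
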