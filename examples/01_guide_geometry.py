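"""Guide geometry: coordinates, editable adenines, codon consequences.

Maps the two built-in AUTS2 exon-10 guides onto hg38 coordinates, lists
which window adenines an ABE can deaminate, and checks that both intended
edits are synonymous at codon level.
"""

from ampliclone import (
    adenine_run_length,
    classify_codon_edit,
    enumerate_editable_positions,
    map_protospacer_position,
)
from ampliclone.auts2 import build_reference, guide_n044, guide_n068

ref = build_reference()

for guide in (guide_n044(), guide_n068()):
    contig, target = map_protospacer_position(guide, guide.target_position)
    editable = enumerate_editable_positions(guide)
    print(f"{guide.guide_id} ({guide.strand} strand): protospacer {guide.protospacer}")
    print(f"  intended edit: protospacer position {guide.target_position} -> {contig}:{target}")
    print(f"  editable window adenines (positions {guide.window[0]}-{guide.window[1]}): {editable}")
    print(f"  adenine run containing the target: {adenine_run_length(guide, guide.target_position)} nt")
    alt = guide.intended_alt_plus
    ce = classify_codon_edit(ref, target, alt)
    print(f"  plus-strand edit {ref.base_at(target)}->{alt}: codon {ce.codon_before}->{ce.codon_after} "
          f"({ce.aa_before}->{ce.aa_after}), synonymous={ce.synonymous}")
    print()

print("A 4-adenine run around the N044 target means protospacer position 4 is a")
print("likely bystander; N068's isolated adenine has no such neighbours.")
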