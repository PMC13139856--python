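"""Rank photoswitch (LOV2) insertion sites on a synthetic inhibitor-partner complex.

Chain A carries a low-confidence coil (an IDR, residues 9-13) followed by a
confident coil (14-16), flanked by helices; chain B sits 15 A away.  The
policy nominates loop residues that are (i) farther than 8 A from every
partner residue and (ii) within two residues of an IDR.  A second, touching
complex shows the negative-control report for an interface-proximal residue.
"""

from optosite import (
    ComplexSpec,
    SegmentBlueprint,
    SitePolicy,
    annotate_negative_controls,
    assign_ss,
    build_complex,
    find_insertion_sites,
    get_plddt_profile,
    interchain_distances,
    interface_profile,
    segment_chain,
)

chain_a = [
    SegmentBlueprint("H", 8, 95.0),
    SegmentBlueprint("C", 5, 70.0),   # IDR: residues 9-13
    SegmentBlueprint("C", 3, 95.0),   # confident loop: residues 14-16
    SegmentBlueprint("H", 8, 95.0),
]
partner = [SegmentBlueprint("H", 10, 95.0)]

model = build_complex(ComplexSpec(chain_a, partner, min_separation=15.0, seed=23))
ss = assign_ss(model, "A")
segments = segment_chain(get_plddt_profile(model, "A"), ss)
profile = interface_profile(interchain_distances(model, "A", "B"))

candidates = find_insertion_sites(segments, ss, profile, SitePolicy())
print("ranked insertion candidates (insertion goes after the residue):")
for c in candidates:
    print(f"  rank {c.rank}: residue {c.seq_id}, interface distance "
          f"{c.interface_distance:.1f} A, gap to {c.nearest_idr_label}: "
          f"{c.gap_to_nearest_idr}")

# negative control on a complex that actually touches (min separation 6 A)
touching = build_complex(ComplexSpec(chain_a, partner, min_separation=6.0, seed=24))
tprofile = interface_profile(interchain_distances(touching, "A", "B"))
closest = min(tprofile.entries, key=lambda e: e[1])[0]
tss = assign_ss(touching, "A")
tsegs = segment_chain(get_plddt_profile(touching, "A"), tss)
report = annotate_negative_controls([closest], tsegs, tss, tprofile, SitePolicy())
a = report[0]
print(f"\nnegative control, residue {a.seq_id}: passes={a.passes}")
for reason in a.failed_criteria:
    print(f"  fails: {reason}")
# Candidates are exactly the loop residues near the IDR and far from the
# partner; the interface-proximal residue is rejected with the reason shown.
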