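"""Call IDR and IOR segments on a synthetic chain with a planted disordered loop.

Builds a helix-coil-helix chain whose middle six residues carry low pLDDT
(70) in the B-factor field, then segments the confidence profile.  The
coil run classifies as an IDR; swapping the coil for a low-confidence
helix yields an IOR instead — a region that is low-confidence yet folded.
"""

from optosite import (
    SegmentBlueprint,
    assign_ss,
    build_chain,
    get_plddt_profile,
    segment_chain,
    segment_summary,
)

for middle in ("C", "H"):
    blueprints = [
        SegmentBlueprint("H", 10, 95.0),
        SegmentBlueprint(middle, 6, 70.0),
        SegmentBlueprint("H", 10, 95.0),
    ]
    model = build_chain(blueprints, seed=42)
    ss = assign_ss(model, "A")
    segments = segment_chain(get_plddt_profile(model, "A"), ss)
    print(f"middle segment type {middle}:")
    for seg in segments:
        print(
            f"  {seg.label}: residues {seg.start}-{seg.end}, "
            f"mean pLDDT {seg.mean_plddt:.1f}, "
            f"structured fraction {seg.structured_fraction:.2f}"
        )
    summary = segment_summary(segments, 26)
    print(f"  IDR fraction of chain: {summary.idr_fraction:.2f}")

# The low-confidence coil (pLDDT < 85, no regular structure) is an IDR;
# the low-confidence helix keeps its fold and is therefore an IOR.
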