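"""Per-residue charge and hydropathy profiles, and segment acidity.

Disordered regions of small Cas9 inhibitors are acid-rich (they mimic DNA
charge); this example profiles a toy sequence with an acidic stretch and
summarizes the acidity of a segment covering it.
"""

from optosite import charge_profile, hydropathy_profile, segment_acidity
from optosite.segmentation import ConfidenceSegment

seq = "MKVLAIKDEDDEGGSRRILFW"

charge = charge_profile(seq, window=5)
hydro = hydropathy_profile(seq, window=9)
print("pos aa  charge  hydropathy")
for i, aa in enumerate(seq):
    print(f"{i + 1:3d}  {aa}  {charge.values[i]:+.2f}   {hydro.values[i]:+.2f}")

segment = ConfidenceSegment("IDR", "A", 8, 14, 70.0, 0.0, "IDR1")
record = segment_acidity([segment], seq)[0]
print(f"\nsegment {record['label']} ({segment.start}-{segment.end}): "
      f"acidic fraction {record['acidic_fraction']:.2f}, "
      f"net charge {record['net_charge']:+.1f}")
# The DEDDDE-rich stretch shows a strongly negative windowed charge and a
# hydropathy dip; the segment summary quantifies both as a fraction and a sum.
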