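# optosite

Insertion-site selection for optogenetic engineering of small proteins,
from predicted structure models.

## The problem

Making a small inhibitor protein — such as an anti-CRISPR (Acr) protein
that blocks dCas9 — light-switchable means splicing a photoreceptor domain
(AsLOV2) into its backbone. A good insertion point must leave inhibition
intact in the dark and let the light-driven unfolding of LOV2's Jα helix
split the host fold under illumination. `optosite` encodes a structural
recipe for finding such points in proteins under ~125 residues, working
entirely from predicted models (AlphaFold-style PDB/mmCIF files that store
the per-residue pLDDT confidence in the B-factor column):

1. **Confidence segmentation.** A residue is low-confidence when
   pLDDT < 85; any maximal run of ≥ 4 such residues is a segment. A run
   without regular structure is an **IDR** (intrinsically disordered
   region); a run that is low-confidence yet folded — majority helix or
   strand — is an **IOR** (intrinsically ordered region).
2. **Secondary structure** from the Cα trace alone (P-SEA-style distance
   and pseudo-angle windows), so the same assigner works on full-atom
   models and backbone-only fixtures. Coil residues form the loop set.
3. **Contact analysis.** The inter-chain residue distance matrix between
   the inhibitor and its partner; pairs at *d* < 8 Å are contacts, and the
   map is refined by dropping partner residues farther than 10 Å from
   every inhibitor residue. Each inhibitor residue gets an interface
   distance: its minimum distance to the partner chain.
4. **Site policy.** Candidate insertion points are loop residues with
   interface distance > 8 Å lying within ≤ 2 residues of an IDR, ranked
   by interface distance (descending), IDR gap, then position. Known
   sites can be assessed as positive/negative controls with the failing
   criterion reported.
5. **Sequence profiles.** Windowed per-residue charge (D/E −1, K/R +1,
   H +0.1) and Kyte–Doolittle hydropathy, plus per-segment acidity
   summaries — disordered Acr regions are characteristically acid-rich.

A synthetic-structure generator builds Cα-trace chains from segment
blueprints (ideal helix: rise 1.5 Å, 100°/residue, radius 2.3 Å; extended
strand; self-avoiding coil) with planted pLDDT profiles, and two-chain
complexes whose minimum inter-chain distance is placed exactly at a
requested value — so every stage is testable offline with known ground
truth.

## Worked example

`examples/03_insertion_sites.py` builds a complex whose inhibitor chain A
is helix(1–8) / low-confidence coil(9–13) / confident coil(14–16) /
helix(17–24), with the partner chain 15 Å away, and prints:

```
ranked insertion candidates (insertion goes after the residue):
  rank 1: residue 9, interface distance 31.9 A, gap to IDR1: 0
  rank 2: residue 10, interface distance 28.9 A, gap to IDR1: 0
  ...
  rank 7: residue 16, interface distance 15.6 A, gap to IDR1: 2
  rank 8: residue 15, interface distance 15.0 A, gap to IDR1: 1

negative control, residue 15: passes=False
  fails: interface_distance <= threshold (6.00 <= 8.0 A)
```

The candidates are exactly the loop residues 9–16: the IDR itself (gap 0)
and the confident loop next to it (gaps 1–2), all beyond the 8 Å interface
threshold. In the second, touching complex (minimum separation 6 Å) the
residue closest to the partner is rejected with the interface-proximity
reason — the behavior expected of a negative-control site.

The other examples show segmentation (an identical low-confidence run
classifies as IDR when coil but IOR when helical), contact-map threshold
semantics at exactly 9 Å, and charge/hydropathy profiling.

## Command line

```sh
optosite simulate --out fixtures --seed 4            # synthetic fixture suite
optosite annotate fixtures/mixed_idr.pdb --out out   # SS + IDR/IOR + profiles
optosite contacts fixtures/complex_touching.pdb --out out
optosite sites fixtures/complex_touching.pdb --acr-chain A --out out
optosite pipeline complex.pdb --acr-chain A --out out
```

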