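# Methods

## Model and rationale

`optosite` operationalizes a structural recipe for choosing photoswitch
(AsLOV2) insertion points in small inhibitor proteins. The underlying
assumptions are:

- AlphaFold-style pLDDT is a usable per-residue disorder proxy even for
  proteins under ~125 residues, provided the calling rule is permissive:
  small proteins rarely show long, deeply low-confidence stretches, so a
  segment is any run of ≥ 4 consecutive residues with pLDDT strictly
  below 85. A residue at exactly 85.0 counts as confident.
- Low confidence does not imply disorder. A low-confidence run that is
  majority helix/strand is called an IOR (intrinsically ordered region)
  rather than an IDR; the majority rule (structured fraction > 0.5,
  exposed as `structured_fraction_cutoff`) is the least-surprising
  formalization for mixed runs, and runs are never split at
  secondary-structure boundaries — spans are reported whole.
- A domain insertion is tolerated in loops away from the binding
  interface and is switchable when adjacent to an IDR. "Away" means the
  residue's minimum distance to any partner residue exceeds 8 Å
  (strictly); "adjacent" means ≤ `max_gap_to_idr` intervening residues
  (default 2), with IDR membership counting as gap 0 — a rule that keeps
  a site one residue away from a disordered loop while excluding
  positions deep inside ordered elements.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `plddt_threshold` | 85 | residues strictly below are low-confidence (0–100 scale) |
| `min_length` | 4 residues | shortest reportable IDR/IOR run |
| `structured_fraction_cutoff` | 0.5 | H/E fraction above which a run is an IOR |
| `contact_threshold` | 8 Å | pairs strictly below are contacts |
| `refine_threshold` | 10 Å | partner residues beyond this everywhere are dropped from the refined map |
| `atom_mode` | CA | distance basis: Cα, Cβ (Cα for Gly), or minimum over heavy atoms |
| `max_gap_to_idr` | 2 residues | intervening residues tolerated between site and IDR |
| `min_interface_distance` | 8 Å | strict lower bound on a candidate's interface distance |
| charge window / hydropathy window | 5 / 9 | sliding-window widths (odd), truncated at chain ends |

Cα is the default distance basis because 8 Å is the community convention
for Cα contact maps; the alternatives exist because interface work often
uses Cβ or heavy-atom minima, and reports record the mode used.

## Secondary structure

Assignment is Cα-only (P-SEA-family geometric rules) so the same code
runs on full-atom predicted models and backbone-only synthetic traces:
helix requires d(i,i+3) ∈ [4.7, 5.5] Å and d(i,i+4) ∈ [5.7, 6.7] Å
(labeling residues i..i+4); strand requires d(i−1,i+1) ∈ [5.7, 7.1] Å
with a pseudo-bond angle ≥ 120° at i. A residue satisfying both is H
(the helix windows are stricter). Two-pass smoothing erases H runs < 4
and E runs < 3. Consecutive Cα gaps > 4.5 Å are chain breaks: criteria
spanning them are void. Residues without the needed context (termini,
missing Cα) are coil. No hydrogen-bond inference, no 3₁₀/π subclasses,
no torsion classes — the labels only have to support the
ordered-vs-disordered distinction and the loop mask.

## Sequence profiles

Charges: D/E −1, K/R +1, H +0.1 (partial protonation near pH 7, a
visible constant), termini ignored, X = 0. Hydropathy uses the
Kyte–Doolittle scale. Windows shrink at chain ends rather than padding
with invented residues. Note that a windowed-mean profile's maximum
absolute value is bounded by the raw per-residue maximum, but widening
the window from, say, 3 to 5 can *increase* the profile maximum (e.g.
AKKARRA); only the bound against raw values is a theorem, and that is
what the property tests assert.

## Synthetic data: what it emulates, and what it does not

The generator emulates the two inputs the pipeline consumes: (i) single
chains with segment-structured pLDDT profiles written to the B-factor
field, as in AlphaFold DB exports, and (ii) two-chain complexes with a
controlled interface geometry. Chains are Cα traces: ideal helix (rise
1.5 Å, 100°/residue, radius 2.3 Å → 3.83 Å steps), near-collinear zigzag
strand at 3.5 Å spacing, and self-avoiding coil walks (3.8 Å steps, turn
angles 60–110° so coil geometry never satisfies the strand windows, no
non-bonded pair under 3.0 Å). Segments are joined with steps in
[3.6, 4.0] Å. Chain B of a complex is rigidly rotated (seeded) and
translated along a random direction by the closed-form amount that puts
the closest inter-chain pair at exactly the requested separation.

Two generator behaviors are deliberate design choices:

- **Planted-truth rejection.** Junction geometry is random, so a rare
  assembly can leak a helix/strand window into a planted coil segment.
  `build_chain` therefore verifies that realized labels carry the
  blueprint's majority truth and otherwise rebuilds from the next seed
  derived from the user's seed (bounded attempts). Generated chains are
  thus guaranteed to be valid ground truth, and generation stays fully
  reproducible from `(blueprints, seed)`.
- **Detectability floor.** Helix/strand segments shorter than 5 residues
  lack the window/run context to be labeled and are exempt from the
  check; consequently planted IOR segments in randomized test chains are
  ≥ 5 residues, while IDR (coil) segments may be the minimum 4.

What the synthetic data does **not** emulate: side chains (so `min_heavy`
mode degenerates to Cα on fixtures), realistic Ramachandran statistics,
pLDDT noise correlated with local packing, crystallographic artifacts,
or genuinely ambiguous half-folded runs. Passing tests therefore show
that the operations implement their definitions exactly on controllable
geometry — not that the 85/8/10 Å thresholds are optimal for any
particular real protein family.

## Numerical choices and degenerate inputs

- Distances are Euclidean; matrices come from `scipy.spatial.cdist`; the
  acceptance oracle recomputes them with an independent double loop.
- Threshold semantics are strict where the definitions say "below"
  (< 8 Å contacts) and inclusive where removal is "above" (≤ 10 Å
  retained).
- Ranking of candidates is lexicographic (interface distance descending,
  IDR gap ascending, seq_id ascending) — the criteria come with no
  natural weights, and lexicographic order is total and deterministic.
- Per-residue pLDDT is read from the Cα B-factor (first atom if no Cα);
  atom-level disagreement > 0.5 within a residue logs a warning. First
  alternate location kept; waters/heteroatoms dropped; insertion codes
  rejected for predicted models. PDB writing enforces the fixed-width
  limits (seq_id ≤ 9999; coordinates 3 decimals, B-factors 2).
- A chain with no IDR yields an empty candidate list, not an error.
- Empty profiles, unknown chains, runs outside the annotation, even
  windows, and out-of-range segments raise `ValueError`/`KeyError`
  subclasses with stage-naming messages in the CLI.

## Problem sizes

The verification suite uses 200 random blueprint chains for planted
segment recovery, 100 random complexes (2–30 residues per chain) for the
brute-force contact oracle, 20 random rigid-body transforms for
invariance checks, and single engineered complexes for the 7/9 Å
boundary cases; the full acceptance run completes in seconds.

## Known limitations

- The secondary-structure assigner is a Cα-geometry heuristic; on real
  models its boundaries can differ by a residue or two from
  hydrogen-bond-based assignments, which shifts structured fractions of
  short runs.
- Nearby low-confidence runs separated by one or two confident residues
  are never merged; whether merging is ever preferable is left to the
  caller via thresholds.
- The site policy scores geometry only: it does not model the inserted
  domain, linker strain, dark/lit-state energetics, or expression-level
  effects, and nominated sites are hypotheses for experimental ranking,
  not predictions of photoswitch performance.
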