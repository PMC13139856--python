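"""Nomination and ranking of optogenetic-domain insertion sites.

A good insertion point for a photoswitch domain (e.g. LOV2) in a small
inhibitor protein is a loop residue that (i) sits away from the binding
interface with the partner protein, so the fusion does not disrupt
inhibition in the dark, and (ii) lies inside or immediately next to an
intrinsically disordered region, so the light-driven unfolding of the
switch can split the host fold.  This module encodes those criteria as an
explicit policy and ranks the residues that satisfy all of them.

"Insertion at residue k" means the domain is spliced into the backbone
after residue k.  Adjacency to an IDR is measured as the number of
intervening residues between k and the nearest IDR span; membership in an
IDR counts as gap 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .contacts import InterfaceProfile
from .secondary_structure import SSAnnotation, loop_mask
from .segmentation import ConfidenceSegment

__all__ = [
    "SitePolicy",
    "InsertionCandidate",
    "SiteAssessment",
    "find_insertion_sites",
    "annotate_negative_controls",
]


@dataclass(frozen=True)
class SitePolicy:
    """Criteria a residue must satisfy to be nominated.

    ``max_gap_to_idr`` counts intervening residues; the default 2 keeps a
    site that is "one residue apart" from an IDR while excluding positions
    deep inside ordered elements.  ``min_interface_distance`` is strict:
    a residue exactly at the threshold is considered interface-proximal.
    """

    max_gap_to_idr: int = 2
    min_interface_distance: float = 8.0
    require_loop: bool = True

    def __post_init__(self) -> None:
        if self.max_gap_to_idr < 0:
            raise ValueError("max_gap_to_idr must be >= 0")


@dataclass
class InsertionCandidate:
    seq_id: int                 # insertion goes after this residue
    interface_distance: float   # min distance to any partner residue, A
    gap_to_nearest_idr: int     # 0 if inside an IDR
    nearest_idr_label: str
    is_loop: bool
    rank: int = 0


@dataclass
class SiteAssessment:
    """Why a queried site passes or fails the policy."""

    seq_id: int
    passes: bool
    failed_criteria: list[str]
    interface_distance: float
    gap_to_nearest_idr: int | None
    is_loop: bool


def _gap_to_idr(seq_id: int, idrs: list[ConfidenceSegment]) -> tuple[int, str]:
    """Intervening-residue count to the nearest IDR and its label."""
    best = None
    best_label = ""
    for seg in idrs:
        if seq_id in seg:
            gap = 0
        elif seq_id < seg.start:
            gap = seg.start - seq_id - 1
        else:
            gap = seq_id - seg.end - 1
        if best is None or gap < best:
            best, best_label = gap, seg.label
    return best, best_label


def find_insertion_sites(
    segments: list[ConfidenceSegment],
    ss: SSAnnotation,
    profile: InterfaceProfile,
    policy: SitePolicy = SitePolicy(),
) -> list[InsertionCandidate]:
    """All residues satisfying the policy, ranked.

    Ranking is lexicographic — interface distance descending (farther from
    the partner is safer), then IDR gap ascending, then seq_id ascending —
    because the criteria come with no natural weights.  Returns an empty
    list when the chain has no IDR segments at all.
    """
    chain_ids = {seg.chain_id for seg in segments} | {ss.chain_id, profile.acr_chain}
    if len(chain_ids) > 1:
        raise ValueError(f"inputs mix chains: {sorted(chain_ids)}")
    idrs = [s for s in segments if s.type == "IDR"]
    if not idrs:
        return []
    loops = loop_mask(ss)
    candidates = []
    for seq_id, dist, _ in profile.entries:
        if policy.require_loop and seq_id not in loops:
            continue
        if not dist > policy.min_interface_distance:
            continue
        gap, label = _gap_to_idr(seq_id, idrs)
        if gap > policy.max_gap_to_idr:
            continue
        candidates.append(
            InsertionCandidate(
                seq_id=seq_id,
                interface_distance=dist,
                gap_to_nearest_idr=gap,
                nearest_idr_label=label,
                is_loop=seq_id in loops,
            )
        )
    candidates.sort(key=lambda c: (-c.interface_distance, c.gap_to_nearest_idr, c.seq_id))
    for rank, c in enumerate(candidates, 1):
        c.rank = rank
    return candidates


def annotate_negative_controls(
    known_sites: list[int],
    segments: list[ConfidenceSegment],
    ss: SSAnnotation,
    profile: InterfaceProfile,
    policy: SitePolicy = SitePolicy(),
) -> list[SiteAssessment]:
    """Assess specific residues against the policy, reporting failures.

    Used to check literature sites or planned controls: for each queried
    position the report states whether it would have been nominated and,
    if not, which criteria it fails (interface proximity, non-loop
    position, or distance from any IDR).
    """
    known = {sid for sid, _, _ in profile.entries}
    idrs = [s for s in segments if s.type == "IDR"]
    loops = loop_mask(ss)
    dist_map = profile.as_dict()
    out = []
    for sid in known_sites:
        if sid not in known:
            raise ValueError(f"site {sid} outside chain {profile.acr_chain}")
        failed: list[str] = []
        dist = dist_map[sid]
        if not dist > policy.min_interface_distance:
            failed.append(
                f"interface_distance <= threshold ({dist:.2f} <= {policy.min_interface_distance} A)"
            )
        is_loop = sid in loops
        if policy.require_loop and not is_loop:
            failed.append("not in a loop")
        if idrs:
            gap, _ = _gap_to_idr(sid, idrs)
            if gap > policy.max_gap_to_idr:
                failed.append(f"gap_to_idr > max ({gap} > {policy.max_gap_to_idr})")
        else:
            gap = None
            failed.append("chain has no IDR segments")
        out.append(
            SiteAssessment(
                seq_id=sid,
                passes=not failed,
                failed_criteria=failed,
                interface_distance=dist,
                gap_to_nearest_idr=gap,
                is_loop=is_loop,
            )
        )
    return out


def candidates_to_tsv(candidates: list[InsertionCandidate], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tinterface_distance\tgap_to_idr\tidr_label\tis_loop\trank\n")
        for c in candidates:
            fh.write(
                f"{c.seq_id}\t{c.interface_distance:.3f}\t{c.gap_to_nearest_idr}\t"
                f"{c.nearest_idr_label}\t{int(c.is_loop)}\t{c.rank}\n"
            )
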