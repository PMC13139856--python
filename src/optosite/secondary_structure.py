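"""C-alpha-only secondary-structure assignment (P-SEA-style).

Assigns helix (H), strand (E) or coil (C) to every residue from the C-alpha
trace alone, which makes the assignment applicable both to full-atom
predicted models and to backbone-only synthetic chains.  Criteria follow
the P-SEA family of geometric rules:

* helix:  d(i, i+3) in [4.7, 5.5] A  and  d(i, i+4) in [5.7, 6.7] A
* strand: d(i-1, i+1) in [5.7, 7.1] A  and a near-linear pseudo-bond angle
  at i (>= 120 deg)

A residue satisfying both sets of windows is labeled H (the helix criteria
are the stricter ones).  Two-pass smoothing then erases H runs shorter
than 4 and E runs shorter than 3.  Criteria spanning a chain break
(consecutive C-alpha gap > 4.5 A) are void, and residues without the
geometric context they need (chain ends, missing C-alpha) default to C.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .structure_io import StructureModel

__all__ = ["SSAnnotation", "assign_ss", "loop_mask"]

HELIX_D13 = (4.7, 5.5)
HELIX_D14 = (5.7, 6.7)
STRAND_D2 = (5.7, 7.1)
STRAND_MIN_ANGLE_DEG = 120.0
CHAIN_BREAK_GAP = 4.5
MIN_HELIX_RUN = 4
MIN_STRAND_RUN = 3


@dataclass
class SSAnnotation:
    """Per-residue helix/strand/coil labels for one chain."""

    chain_id: str
    labels: list[tuple[int, str]]  # (seq_id, label in {H, E, C})

    def label_of(self, seq_id: int) -> str:
        for sid, lab in self.labels:
            if sid == seq_id:
                return lab
        raise KeyError(f"seq_id {seq_id} not in annotation of chain {self.chain_id}")

    def as_dict(self) -> dict[int, str]:
        return dict(self.labels)

    def to_tsv(self, path: str | Path, sequence: str | None = None) -> None:
        with open(path, "w") as fh:
            fh.write("chain\tseq_id\taa\tlabel\n")
            for k, (sid, lab) in enumerate(self.labels):
                aa = sequence[k] if sequence else "."
                fh.write(f"{self.chain_id}\t{sid}\t{aa}\t{lab}\n")


def _in(value: float, band: tuple[float, float]) -> bool:
    return band[0] <= value <= band[1]


def _erase_short_runs(labels: np.ndarray, kind: str, min_run: int) -> None:
    n = len(labels)
    i = 0
    while i < n:
        if labels[i] != kind:
            i += 1
            continue
        j = i
        while j < n and labels[j] == kind:
            j += 1
        if j - i < min_run:
            labels[i:j] = "C"
        i = j


def assign_ss(model: StructureModel, chain_id: str) -> SSAnnotation:
    """Assign H/E/C labels to every residue of ``chain_id``.

    Deterministic and invariant under rigid-body motion of the chain
    (all criteria are inter-atomic distances and angles).
    """
    residues = model.chain(chain_id)
    n = len(residues)
    coords = np.full((n, 3), np.nan)
    for k, r in enumerate(residues):
        ca = r.ca
        if ca is not None:
            coords[k] = ca.coord
    has_ca = ~np.isnan(coords[:, 0])
    if not has_ca.any():
        raise ValueError(f"chain {chain_id}: no C-alpha coordinates")

    # chain breaks: void any criterion whose window spans index k..k+1
    broken_after = np.zeros(n, dtype=bool)
    for k in range(n - 1):
        if not (has_ca[k] and has_ca[k + 1]):
            broken_after[k] = True
        elif np.linalg.norm(coords[k + 1] - coords[k]) > CHAIN_BREAK_GAP:
            broken_after[k] = True

    def window_ok(i: int, j: int) -> bool:
        """True when i..j is inside the chain, has C-alphas, and no break."""
        if i < 0 or j >= n:
            return False
        if not has_ca[i:j + 1].all():
            return False
        return not broken_after[i:j].any()

    def d(i: int, j: int) -> float:
        return float(np.linalg.norm(coords[j] - coords[i]))

    labels = np.full(n, "C", dtype="U1")

    # strand pass first so that the helix pass overwrites on ties (H wins)
    for k in range(1, n - 1):
        if not window_ok(k - 1, k + 1):
            continue
        if not _in(d(k - 1, k + 1), STRAND_D2):
            continue
        v1 = coords[k - 1] - coords[k]
        v2 = coords[k + 1] - coords[k]
        cos_a = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        angle = np.degrees(np.arccos(np.clip(cos_a, -1.0, 1.0)))
        if angle >= STRAND_MIN_ANGLE_DEG:
            labels[k] = "E"

    for k in range(n - 4):
        if not window_ok(k, k + 4):
            continue
        if _in(d(k, k + 3), HELIX_D13) and _in(d(k, k + 4), HELIX_D14):
            labels[k:k + 5] = "H"

    _erase_short_runs(labels, "H", MIN_HELIX_RUN)
    _erase_short_runs(labels, "E", MIN_STRAND_RUN)

    return SSAnnotation(
        chain_id=chain_id,
        labels=[(r.seq_id, str(lab)) for r, lab in zip(residues, labels)],
    )


def loop_mask(ss: SSAnnotation) -> set[int]:
    """Residue numbers labeled coil — the candidate loop positions."""
    return {sid for sid, lab in ss.labels if lab == "C"}
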