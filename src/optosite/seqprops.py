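"""Per-residue charge and hydropathy profiles from primary sequence.

Residue charges at physiological pH: D, E -> -1; K, R -> +1; H -> +0.1
(partial protonation near pH 7); all other residues, including X, 0.
Terminal charges are ignored.  Hydropathy uses the Kyte-Doolittle scale.
Profiles are sliding-window means; windows shrink at the chain ends rather
than padding with invented residues.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .segmentation import ConfidenceSegment

__all__ = [
    "RESIDUE_CHARGE",
    "ChargeProfile",
    "HydropathyProfile",
    "charge_profile",
    "hydropathy_profile",
    "segment_acidity",
]

_STANDARD = set("ACDEFGHIKLMNPQRSTVWY")

RESIDUE_CHARGE = {aa: 0.0 for aa in _STANDARD | {"X"}}
RESIDUE_CHARGE.update({"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.1})


def _windowed_mean(raw: np.ndarray, window: int) -> np.ndarray:
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    half = window // 2
    n = len(raw)
    # cumulative sums give truncated-window means at the ends
    csum = np.concatenate([[0.0], np.cumsum(raw)])
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


def _check_sequence(sequence: str) -> None:
    bad = set(sequence.upper()) - _STANDARD - {"X"}
    if bad:
        raise ValueError(f"non-standard letters in sequence: {sorted(bad)}")


@dataclass
class ChargeProfile:
    sequence: str
    window: int
    values: np.ndarray  # per-residue windowed mean charge, in [-1, 1]

    def to_tsv(self, path: str | Path) -> None:
        _profile_tsv(self.sequence, self.values, path)


@dataclass
class HydropathyProfile:
    sequence: str
    window: int
    values: np.ndarray
    scale_name: str = "Kyte-Doolittle"

    def to_tsv(self, path: str | Path) -> None:
        _profile_tsv(self.sequence, self.values, path)


def _profile_tsv(sequence: str, values: np.ndarray, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("position\taa\tvalue\n")
        for i, (aa, v) in enumerate(zip(sequence, values), 1):
            fh.write(f"{i}\t{aa}\t{v:.4f}\n")


def charge_profile(sequence: str, window: int = 5) -> ChargeProfile:
    """Windowed mean residue charge along the sequence."""
    _check_sequence(sequence)
    seq = sequence.upper()
    raw = np.array([RESIDUE_CHARGE[aa] for aa in seq])
    return ChargeProfile(sequence=seq, window=window, values=_windowed_mean(raw, window))


def hydropathy_profile(sequence: str, window: int = 9) -> HydropathyProfile:
    """Windowed Kyte-Doolittle hydropathy along the sequence (X counts as 0)."""
    _check_sequence(sequence)
    seq = sequence.upper()
    raw = np.array([KYTE_DOOLITTLE.get(aa, 0.0) for aa in seq])
    return HydropathyProfile(sequence=seq, window=window, values=_windowed_mean(raw, window))


def segment_acidity(
    segments: list[ConfidenceSegment], sequence: str
) -> list[dict[str, float | str]]:
    """Acidic-residue fraction and net charge of each segment.

    Segment spans are 1-based inclusive positions into ``sequence``.
    Net charge sums the per-residue charges (so histidines contribute 0.1).
    """
    _check_sequence(sequence)
    seq = sequence.upper()
    out = []
    for seg in segments:
        if seg.start < 1 or seg.end > len(seq):
            raise ValueError(f"segment {seg.label} ({seg.start},{seg.end}) outside sequence")
        sub = seq[seg.start - 1 : seg.end]
        out.append(
            {
                "label": seg.label,
                "type": seg.type,
                "acidic_fraction": sum(1 for aa in sub if aa in "DE") / len(sub),
                "net_charge": float(sum(RESIDUE_CHARGE[aa] for aa in sub)),
            }
        )
    return out
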