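"""Inter-chain residue contact maps and interface distances.

Builds the full residue-residue distance matrix between an inhibitor chain
(e.g. an anti-CRISPR protein) and its partner (e.g. dCas9), calls contacts
below a strict 8 A threshold, refines the map by dropping partner residues
farther than 10 A from every inhibitor residue, and reports per-residue
minimum interface distances — the quantity the insertion-site policy
thresholds on.

Distances are plain Euclidean in Angstrom.  The representative atom is
C-alpha by default (``atom_mode="CA"``); C-beta (falling back to C-alpha
for glycine) and minimum-over-heavy-atoms modes are also available since
interface studies differ on this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import ResidueRecord, StructureModel

__all__ = [
    "ContactParams",
    "ContactMap",
    "InterfaceProfile",
    "interchain_distances",
    "refine_contact_map",
    "interface_profile",
]

AtomMode = Literal["CA", "CB", "min_heavy"]


@dataclass(frozen=True)
class ContactParams:
    contact_threshold: float = 8.0   # pairs strictly below are "in contact"
    refine_threshold: float = 10.0   # partner residues above this everywhere are dropped
    atom_mode: AtomMode = "CA"

    def __post_init__(self) -> None:
        if not 0 < self.contact_threshold <= self.refine_threshold:
            raise ValueError("need 0 < contact_threshold <= refine_threshold")


@dataclass
class ContactMap:
    """Distance matrix (rows = inhibitor residues, cols = partner residues)."""

    acr_chain: str
    partner_chain: str
    acr_residues: list[int]
    partner_residues: list[int]
    distances: np.ndarray  # (len(acr), len(partner)), Angstrom
    params: ContactParams

    @property
    def contacts(self) -> set[tuple[int, int]]:
        ii, jj = np.nonzero(self.distances < self.params.contact_threshold)
        return {(self.acr_residues[i], self.partner_residues[j]) for i, j in zip(ii, jj)}

    @property
    def refined_partner_residues(self) -> list[int]:
        if self.distances.size == 0:
            return []
        keep = self.distances.min(axis=0) <= self.params.refine_threshold
        return [sid for sid, k in zip(self.partner_residues, keep) if k]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("seq_id\t" + "\t".join(map(str, self.partner_residues)) + "\n")
            for sid, row in zip(self.acr_residues, self.distances):
                fh.write(str(sid) + "\t" + "\t".join(f"{d:.3f}" for d in row) + "\n")

    def contacts_to_tsv(self, path: str | Path) -> None:
        """Long-format contact list: acr_res, partner_res, distance."""
        idx_a = {sid: i for i, sid in enumerate(self.acr_residues)}
        idx_p = {sid: j for j, sid in enumerate(self.partner_residues)}
        with open(path, "w") as fh:
            fh.write("acr_res\tpartner_res\tdistance\n")
            for a, p in sorted(self.contacts):
                fh.write(f"{a}\t{p}\t{self.distances[idx_a[a], idx_p[p]]:.3f}\n")


@dataclass
class InterfaceProfile:
    """Per-inhibitor-residue minimum distance to the partner chain."""

    acr_chain: str
    entries: list[tuple[int, float, bool]]  # (seq_id, min_distance, in_contact)

    def min_distance(self, seq_id: int) -> float:
        for sid, dist, _ in self.entries:
            if sid == seq_id:
                return dist
        raise KeyError(f"seq_id {seq_id} not in interface profile")

    def as_dict(self) -> dict[int, float]:
        return {sid: dist for sid, dist, _ in self.entries}


def _representative_coords(residues: list[ResidueRecord], mode: AtomMode) -> np.ndarray:
    """One coordinate per residue for CA/CB modes; raises if unresolvable."""
    coords = []
    for r in residues:
        atom = None
        if mode == "CB":
            atom = r.atom("CB") or r.ca  # glycine has no CB
        else:
            atom = r.ca or (r.atoms[0] if r.atoms else None)
        if atom is None:
            raise ValueError(f"residue {r.chain_id}{r.seq_id}: no usable atom for mode {mode}")
        coords.append(atom.coord)
    return np.asarray(coords)


def _min_heavy_matrix(a: list[ResidueRecord], b: list[ResidueRecord]) -> np.ndarray:
    out = np.empty((len(a), len(b)))
    bcoords = [np.array([at.coord for at in r.atoms if at.element != "H"]) for r in b]
    for i, ra in enumerate(a):
        ac = np.array([at.coord for at in ra.atoms if at.element != "H"])
        if ac.size == 0:
            raise ValueError(f"residue {ra.chain_id}{ra.seq_id}: no heavy atoms")
        for j, bc in enumerate(bcoords):
            if bc.size == 0:
                raise ValueError(f"residue {b[j].chain_id}{b[j].seq_id}: no heavy atoms")
            out[i, j] = cdist(ac, bc).min()
    return out


def interchain_distances(
    model: StructureModel,
    acr_chain: str,
    partner_chain: str,
    params: ContactParams = ContactParams(),
) -> ContactMap:
    """Full inter-chain residue distance matrix with contact calls."""
    res_a = model.chain(acr_chain)
    res_b = model.chain(partner_chain)
    if params.atom_mode == "min_heavy":
        dist = _min_heavy_matrix(res_a, res_b)
    else:
        dist = cdist(
            _representative_coords(res_a, params.atom_mode),
            _representative_coords(res_b, params.atom_mode),
        )
    return ContactMap(
        acr_chain=acr_chain,
        partner_chain=partner_chain,
        acr_residues=[r.seq_id for r in res_a],
        partner_residues=[r.seq_id for r in res_b],
        distances=dist,
        params=params,
    )


def refine_contact_map(cmap: ContactMap, params: ContactParams | None = None) -> ContactMap:
    """Restrict the partner dimension to residues within the refine threshold.

    Partner residues farther than ``refine_threshold`` from every inhibitor
    residue are removed.  Contacts are unaffected: every contacting pair is
    below the (smaller) contact threshold and therefore survives.
    """
    p = params or cmap.params
    base = replace(cmap, params=p)
    keep_ids = set(base.refined_partner_residues)
    keep_idx = [j for j, sid in enumerate(cmap.partner_residues) if sid in keep_ids]
    return ContactMap(
        acr_chain=cmap.acr_chain,
        partner_chain=cmap.partner_chain,
        acr_residues=list(cmap.acr_residues),
        partner_residues=[cmap.partner_residues[j] for j in keep_idx],
        distances=cmap.distances[:, keep_idx] if keep_idx else np.empty((len(cmap.acr_residues), 0)),
        params=p,
    )


def interface_profile(cmap: ContactMap) -> InterfaceProfile:
    """Row-minimum distances: each inhibitor residue's distance to the interface."""
    entries = []
    for i, sid in enumerate(cmap.acr_residues):
        if cmap.distances.shape[1] == 0:
            dmin = float("inf")
        else:
            dmin = float(cmap.distances[i].min())
        entries.append((sid, dmin, dmin < cmap.params.contact_threshold))
    return InterfaceProfile(acr_chain=cmap.acr_chain, entries=entries)
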