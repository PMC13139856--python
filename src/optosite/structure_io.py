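"""Reading and writing protein structure models with per-residue pLDDT.

Predicted models (AlphaFold-style PDB/mmCIF exports) store the per-residue
confidence score (pLDDT, 0-100) in the B-factor column of every atom.  This
module parses such files into a light in-memory model exposing chains,
residues, coordinates and the per-residue pLDDT, and writes models back to
fixed-width PDB.

Parsing is delegated to :mod:`gemmi`; this module owns the model-level
policies: first alternate location kept, waters and heteroatoms dropped,
the residue pLDDT taken from the C-alpha atom (falling back to the first
atom when no C-alpha is present).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "StructureModel",
    "StructureError",
    "read_structure",
    "write_structure",
    "get_plddt_profile",
]


class StructureError(ValueError):
    """Raised for unreadable, empty or unwritable structure files."""


# 3-letter -> 1-letter for the 20 standard residues; everything else -> X
_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}
_ONE_TO_THREE["X"] = "UNK"


@dataclass
class AtomRecord:
    """One atom: name, element, Cartesian coordinates (A) and B-factor.

    For predicted models the B-factor carries the residue's pLDDT score.
    """

    name: str
    element: str
    coord: np.ndarray  # shape (3,), Angstrom
    b_factor: float
    alt_loc: str = ""

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise StructureError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if self.b_factor < 0:
            raise StructureError(f"atom {self.name}: negative B-factor {self.b_factor}")


@dataclass
class ResidueRecord:
    """One polymer residue with its atoms and a single pLDDT value.

    ``seq_id`` is the author residue number (1-based as authored); ``aa`` is
    the one-letter code, ``X`` for nonstandard residues.
    """

    chain_id: str
    seq_id: int
    aa: str
    atoms: list[AtomRecord]
    plddt: float

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> AtomRecord | None:
        return self.atom("CA")


@dataclass
class StructureModel:
    """Chains of residues parsed from one structure file."""

    chains: dict[str, list[ResidueRecord]] = field(default_factory=dict)
    source: Literal["predicted", "experimental"] = "predicted"
    title: str = ""

    def chain(self, chain_id: str) -> list[ResidueRecord]:
        if chain_id not in self.chains:
            raise KeyError(f"no chain {chain_id!r}; available: {sorted(self.chains)}")
        return self.chains[chain_id]

    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def __iter__(self) -> Iterator[tuple[str, list[ResidueRecord]]]:
        return iter(self.chains.items())

    def validate(self) -> None:
        if not self.chains:
            raise StructureError("model has no chains")
        for cid, residues in self.chains.items():
            if not residues:
                raise StructureError(f"chain {cid} is empty")
            ids = [r.seq_id for r in residues]
            if any(b <= a for a, b in zip(ids, ids[1:])):
                raise StructureError(f"chain {cid}: residue numbering not strictly increasing")


def _residue_plddt(atoms: list[AtomRecord]) -> float:
    """Representative per-residue value: C-alpha B-factor, else first atom.

    Predicted models write one value per residue, so atom-level disagreement
    above 0.5 indicates an unexpected file; it is logged, and the C-alpha
    value kept.
    """
    bvals = [a.b_factor for a in atoms]
    if max(bvals) - min(bvals) > 0.5:
        logger.warning("atoms of one residue disagree on B-factor by >0.5; keeping CA value")
    for a in atoms:
        if a.name == "CA":
            return a.b_factor
    return atoms[0].b_factor


def read_structure(
    path: str | Path,
    format: Literal["pdb", "mmcif", "auto"] = "auto",
    source: Literal["predicted", "experimental"] = "predicted",
) -> StructureModel:
    """Parse a PDB or mmCIF file into a :class:`StructureModel`.

    All polymer chains are returned; waters and heteroatoms are dropped and
    only the first alternate conformation is kept.  Per-residue ``plddt``
    is populated from the B-factor column.  Insertion codes are rejected
    for ``source="predicted"`` (AlphaFold exports never carry them) and
    suffix-sorted into the author numbering for experimental models.

    Raises
    ------
    StructureError
        If the file cannot be parsed or contains no polymer residues.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    fmt_map = {
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "auto": gemmi.CoorFormat.Detect,
    }
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            st = gemmi.read_structure(str(path), format=fmt_map[format])
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc

    st.setup_entities()
    st.remove_waters()
    st.remove_alternative_conformations()  # keeps the first alt-loc

    model = StructureModel(source=source, title=st.name or "")
    gm = st[0]
    for chain in gm:
        residues: list[ResidueRecord] = []
        for res in chain:
            info = gemmi.find_tabulated_residue(res.name)
            is_aa = info is not None and info.is_amino_acid()
            if not is_aa:
                continue  # heteroatoms, ligands, nucleic acids
            if res.seqid.icode.strip():
                if source == "predicted":
                    raise StructureError(
                        f"insertion code {res.seqid.icode!r} at {chain.name}{res.seqid.num}: "
                        "not allowed in predicted models"
                    )
            atoms = [
                AtomRecord(
                    name=a.name,
                    element=a.element.name,
                    coord=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    b_factor=a.b_iso,
                    alt_loc=a.altloc if a.altloc != "\x00" else "",
                )
                for a in res
            ]
            if not atoms:
                continue
            residues.append(
                ResidueRecord(
                    chain_id=chain.name,
                    seq_id=res.seqid.num,
                    aa=_THREE_TO_ONE.get(res.name, "X"),
                    atoms=atoms,
                    plddt=_residue_plddt(atoms),
                )
            )
        if residues:
            model.chains[chain.name] = residues

    if not model.chains:
        raise StructureError(f"{path}: no polymer residues found")
    model.validate()
    if source == "predicted":
        for cid, residues in model.chains.items():
            for r in residues:
                if not 0.0 <= r.plddt <= 100.0:
                    raise StructureError(
                        f"chain {cid} residue {r.seq_id}: pLDDT {r.plddt} outside [0, 100]"
                    )
    return model


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a model as fixed-width PDB (v3.3 ATOM/TER/END records).

    Coordinates survive the round trip to 3 decimals and B-factors to 2
    (the fixed-width column limits).  Residue numbers above 9999 do not fit
    the format and raise :class:`StructureError`.
    """
    model.validate()
    st = gemmi.Structure()
    st.name = model.title or "optosite model"
    gm = gemmi.Model("1")
    for cid, residues in model.chains.items():
        chain = gemmi.Chain(cid)
        for r in residues:
            if r.seq_id > 9999 or r.seq_id < -999:
                raise StructureError(
                    f"residue number {r.seq_id} does not fit fixed-width PDB columns"
                )
            res = gemmi.Residue()
            res.name = _ONE_TO_THREE.get(r.aa, "UNK")
            res.seqid = gemmi.SeqId(r.seq_id, " ")
            for a in r.atoms:
                atom = gemmi.Atom()
                atom.name = a.name
                atom.element = gemmi.Element(a.element)
                atom.pos = gemmi.Position(*a.coord)
                atom.b_iso = a.b_factor
                atom.occ = 1.0
                res.add_atom(atom)
            chain.add_residue(res)
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    try:
        st.write_pdb(str(path))
    except (OSError, RuntimeError) as exc:
        raise StructureError(f"cannot write {path}: {exc}") from exc


def get_plddt_profile(model: StructureModel, chain_id: str) -> list[tuple[int, float]]:
    """Per-residue ``(seq_id, plddt)`` pairs for one chain, in sequence order."""
    return [(r.seq_id, r.plddt) for r in model.chain(chain_id)]


def chain_sequence(model: StructureModel, chain_id: str) -> str:
    """One-letter sequence of a chain, in residue order."""
    return "".join(r.aa for r in model.chain(chain_id))
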