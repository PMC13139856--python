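"""Synthetic C-alpha-trace chains and complexes with planted ground truth.

Fixtures for every downstream stage are generated, not downloaded: single
chains assembled from segment blueprints (ideal helix / extended strand /
self-avoiding coil, each with a planted per-residue pLDDT written to the
B-factor field) and two-chain complexes whose minimum inter-chain C-alpha
distance is placed exactly at a requested value.  All geometry is analytic
or seeded, so the planted secondary structure, confidence segments and
contact expectations are known by construction and recorded in a manifest.

Geometry constants: ideal helix rise 1.5 A, 100 deg/residue, radius 2.3 A
(step 3.83 A); strand a near-collinear zigzag at 3.5 A spacing; coil a
self-avoiding walk with 3.8 A steps, turn angles in [60, 110] deg (so coil
never mimics strand geometry) and no non-bonded pair closer than 3.0 A.
Segments are joined with a C-alpha step in [3.6, 4.0] A.  A chain whose
realized secondary-structure labels would not match the blueprint (rare
junction artefacts) is rejected and rebuilt from the next derived seed, so
generated chains always carry their planted truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .secondary_structure import assign_ss
from .structure_io import AtomRecord, ResidueRecord, StructureModel, write_structure

__all__ = [
    "SegmentBlueprint",
    "ComplexSpec",
    "GenerationError",
    "build_chain",
    "build_complex",
    "random_blueprint_chain",
    "write_fixture_suite",
]

HELIX_RISE = 1.5
HELIX_TWIST_DEG = 100.0
HELIX_RADIUS = 2.3
STRAND_STEP = 3.5
STRAND_ZIGZAG = 0.8
COIL_STEP = 3.8
CLASH_DISTANCE = 3.0
JOIN_STEP = (3.6, 4.0)
COIL_TURN_DEG = (60.0, 110.0)
MAX_CHAIN_ATTEMPTS = 80
MAX_WALK_ATTEMPTS = 200


class GenerationError(RuntimeError):
    pass


@dataclass
class SegmentBlueprint:
    """One planned segment: secondary structure, length, planted pLDDT."""

    ss_type: str  # H, E or C
    length: int
    plddt: float | list[float] = 95.0
    aa: str | None = None  # one-letter string of len(length); default poly-Ala

    def __post_init__(self) -> None:
        if self.ss_type not in ("H", "E", "C"):
            raise ValueError(f"ss_type must be H/E/C, got {self.ss_type!r}")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.aa is not None and len(self.aa) != self.length:
            raise ValueError("aa string length must equal segment length")
        vals = self.plddt_values()
        if any(not 0.0 <= v <= 100.0 for v in vals):
            raise ValueError("plddt must be within [0, 100]")

    def plddt_values(self) -> list[float]:
        if isinstance(self.plddt, (int, float)):
            return [float(self.plddt)] * self.length
        if len(self.plddt) != self.length:
            raise ValueError("per-residue plddt list length must equal segment length")
        return [float(v) for v in self.plddt]


@dataclass
class ComplexSpec:
    chain_a: list[SegmentBlueprint]
    chain_b: list[SegmentBlueprint]
    min_separation: float  # target minimum inter-chain C-alpha distance, A
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_separation <= 0:
            raise ValueError("min_separation must be > 0")


def _helix_coords(n: int) -> np.ndarray:
    k = np.arange(n)
    ang = np.radians(HELIX_TWIST_DEG) * k
    return np.column_stack(
        [HELIX_RADIUS * np.cos(ang), HELIX_RADIUS * np.sin(ang), HELIX_RISE * k]
    )


def _strand_coords(n: int) -> np.ndarray:
    dx = math.sqrt(STRAND_STEP**2 - STRAND_ZIGZAG**2)
    k = np.arange(n)
    return np.column_stack([dx * k, STRAND_ZIGZAG * (k % 2), np.zeros(n)])


def _turn_step(prev_dir: np.ndarray, rng: np.random.Generator,
               step: float, turn_deg: tuple[float, float]) -> np.ndarray:
    """A step of given length whose angle to ``prev_dir`` is in the turn band."""
    theta = np.radians(rng.uniform(*turn_deg))
    phi = rng.uniform(0, 2 * np.pi)
    # orthonormal frame around prev_dir
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, prev_dir)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(prev_dir, ref)
    u /= np.linalg.norm(u)
    v = np.cross(prev_dir, u)
    direction = (
        math.cos(theta) * prev_dir
        + math.sin(theta) * (math.cos(phi) * u + math.sin(phi) * v)
    )
    return step * direction


def _coil_coords(n: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded self-avoiding walk; 3.8 A steps, no non-bonded pair < 3.0 A."""
    for _ in range(MAX_WALK_ATTEMPTS):
        pts = [np.zeros(3)]
        d = rng.standard_normal(3)
        d /= np.linalg.norm(d)
        ok = True
        for _k in range(1, n):
            placed = False
            for _try in range(40):
                step = _turn_step(d, rng, COIL_STEP, COIL_TURN_DEG) if len(pts) > 1 \
                    else COIL_STEP * d
                cand = pts[-1] + step
                others = np.array(pts[:-1]) if len(pts) > 1 else None
                if others is None or cdist(cand[None], others).min() >= CLASH_DISTANCE:
                    new_dir = step / np.linalg.norm(step)
                    pts.append(cand)
                    d = new_dir
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return np.asarray(pts)
    raise GenerationError(f"self-avoiding walk of length {n} failed to place")


_SEGMENT_BUILDERS = {"H": _helix_coords, "E": _strand_coords}


def _assemble_coords(blueprints: list[SegmentBlueprint], rng: np.random.Generator) -> np.ndarray:
    """Place segments sequentially with clash checks; raises on failure."""
    points: list[np.ndarray] = []
    for bp in blueprints:
        local = (_SEGMENT_BUILDERS[bp.ss_type](bp.length) if bp.ss_type in _SEGMENT_BUILDERS
                 else _coil_coords(bp.length, rng))
        local = local - local[0]
        for _try in range(60):
            rot = Rotation.random(rng=rng).as_matrix()
            placed = local @ rot.T
            if not points:
                offset = np.zeros(3)
            else:
                if len(points) > 1:
                    prev_dir = points[-1] - points[-2]
                    prev_dir /= np.linalg.norm(prev_dir)
                else:
                    prev_dir = rng.standard_normal(3)
                    prev_dir /= np.linalg.norm(prev_dir)
                step = _turn_step(prev_dir, rng, rng.uniform(*JOIN_STEP), COIL_TURN_DEG)
                offset = points[-1] + step
            placed = placed + offset
            if points:
                dmat = cdist(placed, np.array(points))
                dmat[0, -1] = np.inf  # junction bond is not a clash
                if dmat.min() < CLASH_DISTANCE:
                    continue
            points.extend(placed)
            break
        else:
            raise GenerationError("segment placement failed after bounded retries")
    return np.asarray(points)


def _labels_match_blueprint(model: StructureModel, chain_id: str,
                            blueprints: list[SegmentBlueprint]) -> bool:
    """Planted-truth check: realized SS majority agrees with each segment.

    For H/E segments long enough to be detectable (>= 5 residues; shorter
    ones lack the geometric window/run context) the planted label must hold
    on a strict majority of residues; for C segments, structured labels
    must not reach a majority (so a low-confidence coil segment always
    classifies as disordered).
    """
    ann = assign_ss(model, chain_id)
    labels = [lab for _, lab in ann.labels]
    pos = 0
    for bp in blueprints:
        seg = labels[pos:pos + bp.length]
        pos += bp.length
        n_struct = sum(1 for l in seg if l in ("H", "E"))
        if bp.ss_type == "C":
            if n_struct / bp.length > 0.5:
                return False
        elif bp.length >= 5:
            if sum(1 for l in seg if l == bp.ss_type) / bp.length <= 0.5:
                return False
    return True


def _model_from_coords(coords: np.ndarray, blueprints: list[SegmentBlueprint],
                       chain_id: str) -> StructureModel:
    plddts: list[float] = []
    aas: list[str] = []
    for bp in blueprints:
        plddts.extend(bp.plddt_values())
        aas.extend(bp.aa if bp.aa else "A" * bp.length)
    residues = [
        ResidueRecord(
            chain_id=chain_id,
            seq_id=k + 1,
            aa=aas[k],
            atoms=[AtomRecord(name="CA", element="C", coord=coords[k], b_factor=plddts[k])],
            plddt=plddts[k],
        )
        for k in range(len(coords))
    ]
    return StructureModel(chains={chain_id: residues}, source="predicted",
                          title="synthetic C-alpha trace")


def build_chain(blueprints: list[SegmentBlueprint], seed: int = 0,
                chain_id: str = "A") -> StructureModel:
    """Build a single-chain C-alpha-trace model from segment blueprints.

    Fully reproducible from ``(blueprints, seed)``.  Chains are rebuilt
    from successive derived seeds until the realized secondary structure
    carries the blueprint's planted labels (see module docstring); raises
    :class:`GenerationError` with the seed reported if that never happens.
    """
    if not blueprints:
        raise ValueError("need at least one blueprint segment")
    base = np.random.SeedSequence(seed)
    for child in base.spawn(MAX_CHAIN_ATTEMPTS):
        rng = np.random.default_rng(child)
        try:
            coords = _assemble_coords(blueprints, rng)
        except GenerationError:
            continue
        model = _model_from_coords(coords, blueprints, chain_id)
        if _labels_match_blueprint(model, chain_id, blueprints):
            return model
    raise GenerationError(f"chain generation failed for seed {seed}")


def build_complex(spec: ComplexSpec) -> StructureModel:
    """Two-chain model with exact minimum inter-chain C-alpha distance.

    Chain B is rigidly rotated (seeded) and translated along a random
    direction so that the closest A-B C-alpha pair sits at exactly
    ``spec.min_separation`` (well within the +-0.5 A placement contract).
    """
    model_a = build_chain(spec.chain_a, seed=spec.seed * 2 + 1, chain_id="A")
    model_b = build_chain(spec.chain_b, seed=spec.seed * 2 + 2, chain_id="B")
    xa = np.array([r.ca.coord for r in model_a.chain("A")])
    xb0 = np.array([r.ca.coord for r in model_b.chain("B")])
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0xC0)))
    s = spec.min_separation
    for _try in range(100):
        rot = Rotation.random(rng=rng).as_matrix()
        xb = (xb0 - xb0.mean(axis=0)) @ rot.T + xa.mean(axis=0)
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        # smallest t with ||d - t*u|| >= s for every pair d = a - b:
        # per pair the larger quadratic root, maximized over pairs
        diffs = xa[:, None, :] - xb[None, :, :]       # (na, nb, 3)
        proj = diffs @ u                               # d . u
        disc = proj**2 - (diffs**2).sum(axis=2) + s**2
        mask = disc >= 0
        if not mask.any():
            continue  # every pair stays beyond s along this direction; re-draw
        t = float((proj[mask] + np.sqrt(disc[mask])).max())
        xb_final = xb + t * u
        realized = cdist(xa, xb_final).min()
        if abs(realized - s) < 1e-6:
            break
    else:
        raise GenerationError(f"complex placement failed for seed {spec.seed}")
    for r, coord in zip(model_b.chain("B"), xb_final):
        r.atoms[0].coord = coord
    return StructureModel(
        chains={"A": model_a.chain("A"), "B": model_b.chain("B")},
        source="predicted",
        title=f"synthetic complex, min separation {s:.2f} A",
    )


def random_blueprint_chain(
    rng: np.random.Generator,
    n_low_segments: tuple[int, int] = (1, 3),
    threshold: float = 85.0,
    margin: float = 5.0,
) -> tuple[list[SegmentBlueprint], list[dict]]:
    """Random blueprints with known low-confidence segments.

    Alternates confident segments (pLDDT >= threshold + margin) with
    low-confidence ones (pLDDT <= threshold - margin) so the expected
    IDR/IOR spans are unambiguous.  Returns the blueprints and the planted
    truth: a dict per low segment with 1-based ``start``/``end`` and
    ``type`` (C plants an IDR, H/E plant an IOR).
    """
    blueprints: list[SegmentBlueprint] = []
    expected: list[dict] = []
    pos = 1

    def high_segment() -> SegmentBlueprint:
        return SegmentBlueprint(
            ss_type=rng.choice(["H", "E", "C"]),
            length=int(rng.integers(5, 13)),
            plddt=float(rng.uniform(threshold + margin, 99.0)),
        )

    n_low = int(rng.integers(n_low_segments[0], n_low_segments[1] + 1))
    for _ in range(n_low):
        hi = high_segment()
        blueprints.append(hi)
        pos += hi.length
        ss = str(rng.choice(["H", "E", "C"]))
        length = int(rng.integers(4, 11)) if ss == "C" else int(rng.integers(5, 11))
        lo = SegmentBlueprint(
            ss_type=ss, length=length,
            plddt=float(rng.uniform(40.0, threshold - margin)),
        )
        blueprints.append(lo)
        expected.append({
            "start": pos, "end": pos + length - 1,
            "type": "IDR" if ss == "C" else "IOR",
        })
        pos += length
    blueprints.append(high_segment())
    return blueprints, expected


# canonical fixtures: blueprints shared by the test suite and the CLI
CANONICAL_CHAINS = {
    "helix": [SegmentBlueprint("H", 15, 95.0)],
    "strand": [SegmentBlueprint("E", 10, 95.0)],
    "mixed_idr": [SegmentBlueprint("H", 10, 95.0), SegmentBlueprint("C", 6, 70.0),
                  SegmentBlueprint("H", 10, 95.0)],
    "mixed_ior": [SegmentBlueprint("H", 10, 95.0), SegmentBlueprint("H", 6, 70.0),
                  SegmentBlueprint("H", 10, 95.0)],
}

CANONICAL_COMPLEX_SEPARATIONS = {"far": 50.0, "margin": 9.0, "touching": 6.0}


def write_fixture_suite(outdir: str | Path, seed: int = 0) -> dict:
    """Emit the canonical fixtures as PDB plus a JSON manifest of truths.

    Byte-identical on re-run with the same seed.  The manifest records, per
    fixture, the planted confidence segments and (for complexes) the target
    minimum separation and the contact expectations at the default 8/10 A
    thresholds.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "chains": {}, "complexes": {}}

    for name, bps in CANONICAL_CHAINS.items():
        model = build_chain(bps, seed=seed)
        write_structure(model, outdir / f"{name}.pdb")
        segments = []
        pos = 1
        for bp in bps:
            vals = bp.plddt_values()
            if all(v < 85.0 for v in vals):
                segments.append({
                    "start": pos, "end": pos + bp.length - 1,
                    "type": "IDR" if bp.ss_type == "C" else "IOR",
                })
            pos += bp.length
        manifest["chains"][name] = {
            "file": f"{name}.pdb",
            "n_residues": sum(bp.length for bp in bps),
            "planted_segments": segments,
        }

    chain_bps = [SegmentBlueprint("H", 8, 95.0), SegmentBlueprint("C", 5, 70.0),
                 SegmentBlueprint("H", 8, 95.0)]
    for name, sep in CANONICAL_COMPLEX_SEPARATIONS.items():
        spec = ComplexSpec(chain_a=chain_bps, chain_b=[SegmentBlueprint("H", 10, 95.0)],
                           min_separation=sep, seed=seed)
        model = build_complex(spec)
        write_structure(model, outdir / f"complex_{name}.pdb")
        manifest["complexes"][name] = {
            "file": f"complex_{name}.pdb",
            "min_separation": sep,
            "expect_contacts": sep < 8.0,
            "expect_refined_partners": sep <= 10.0,
        }

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
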