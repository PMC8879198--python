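"""Atomic models: PDB I/O, rigid transforms, superposition and TM-score.

Models are flat ordered atom lists (chains are contiguous blocks), which is
the natural container for the coarse-grained C-alpha traces used throughout
the toolkit, while still round-tripping all-atom PDB files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

from emfit.errors import (
    DegenerateInputError,
    EmptyModelError,
    FormatOverflowError,
)

__all__ = [
    "Atom", "AtomicModel", "RigidTransform",
    "read_pdb", "write_pdb", "superpose_kabsch", "tm_score",
]


@dataclass(frozen=True)
class Atom:
    """One atom: chain/residue identity plus a position in Angstrom."""

    chain_id: str
    residue_index: int
    residue_name: str
    atom_name: str
    element: str
    position: tuple[float, float, float]
    b_factor: float = 0.0

    def __post_init__(self):
        if not all(math.isfinite(c) for c in self.position):
            raise ValueError(f"non-finite atom position {self.position}")


@dataclass
class AtomicModel:
    """Ordered atom list with free-form metadata.

    Chains must form contiguous blocks in atom order; ``N = len(atoms)``
    is the heavy-atom count used by the map-bias energy.
    """

    atoms: list[Atom]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.atoms) == 0:
            raise EmptyModelError("model must contain at least one atom")
        seen, prev = set(), None
        for a in self.atoms:
            if a.chain_id != prev:
                if a.chain_id in seen:
                    raise ValueError(
                        f"chain {a.chain_id!r} is not a contiguous block")
                seen.add(a.chain_id)
                prev = a.chain_id

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) float64 coordinate array in Angstrom."""
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def chain_ids(self) -> list[str]:
        out, prev = [], None
        for a in self.atoms:
            if a.chain_id != prev:
                out.append(a.chain_id)
                prev = a.chain_id
        return out

    def chain_slices(self) -> dict[str, slice]:
        """Start/stop atom-index slice of each contiguous chain block."""
        out: dict[str, slice] = {}
        start, prev = 0, None
        for i, a in enumerate(self.atoms):
            if a.chain_id != prev:
                if prev is not None:
                    out[prev] = slice(start, i)
                start, prev = i, a.chain_id
        out[prev] = slice(start, len(self.atoms))
        return out

    def ca_indices(self) -> np.ndarray:
        return np.array(
            [i for i, a in enumerate(self.atoms) if a.atom_name == "CA"],
            dtype=int)

    def with_coords(self, coords: np.ndarray) -> "AtomicModel":
        """Copy of the model with replaced coordinates (same topology)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [replace(a, position=tuple(xyz))
                 for a, xyz in zip(self.atoms, coords)]
        return AtomicModel(atoms, dict(self.metadata))

    def transformed(self, t: "RigidTransform") -> "AtomicModel":
        return self.with_coords(t.apply(self.coords))


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t (rotation matrix + translation, A)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not math.isclose(float(np.linalg.det(R)), 1.0, abs_tol=1e-8):
            raise ValueError("rotation determinant is not +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T,
                              -(self.rotation.T @ self.translation))

    def rotation_angle_deg(self) -> float:
        """Geodesic magnitude of the rotation part, degrees."""
        return float(np.degrees(
            Rotation.from_matrix(self.rotation).magnitude()))


def read_pdb(path) -> AtomicModel:
    """Read an atomic model from a PDB file.

    First NMR/crystallographic model only; first altloc kept; hydrogen and
    deuterium records dropped (the density model counts heavy atoms).
    HETATM records are kept, with their atom indices listed in
    ``metadata["hetatm_indices"]``.
    """
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, SystemError, FileNotFoundError) as exc:
        raise OSError(f"cannot read PDB file {path}: {exc}") from exc
    atoms: list[Atom] = []
    het: list[int] = []
    if len(st) == 0:
        raise EmptyModelError(f"no coordinate records in {path}")
    model = st[0]
    for chain in model:
        for res in chain:
            seen_names: set[str] = set()
            for at in res:
                if at.element.is_hydrogen:
                    continue
                if at.altloc not in ("", "\0") and at.name in seen_names:
                    continue  # keep first altloc only
                seen_names.add(at.name)
                if res.het_flag == "H":
                    het.append(len(atoms))
                atoms.append(Atom(
                    chain_id=chain.name,
                    residue_index=res.seqid.num,
                    residue_name=res.name,
                    atom_name=at.name,
                    element=at.element.name,
                    position=(at.pos.x, at.pos.y, at.pos.z),
                    b_factor=at.b_iso,
                ))
    if not atoms:
        raise EmptyModelError(f"no coordinate records in {path}")
    meta = {"source": str(path)}
    if het:
        meta["hetatm_indices"] = het
    return AtomicModel(atoms, meta)


def write_pdb(model: AtomicModel, path) -> None:
    """Write a model as fixed-column PDB with a TER record after each chain.

    Raises :class:`FormatOverflowError` when a coordinate does not fit the
    8.3 fixed field (|x| >= 10000, or below -999.999).
    """
    coords = model.coords
    if np.any(coords >= 10000.0) or np.any(coords <= -1000.0):
        raise FormatOverflowError(
            "coordinate out of PDB fixed-column range (-999.999..9999.999)")
    st = gemmi.Structure()
    gm = gemmi.Model("1")
    het = set(model.metadata.get("hetatm_indices", ()))
    for cid, sl in model.chain_slices().items():
        chain = gemmi.Chain(cid)
        # group contiguous atoms into residues, build each fully before
        # adding (gemmi copies on add_residue)
        groups: list[list[int]] = []
        prev_key = None
        for i in range(sl.start, sl.stop):
            a = model.atoms[i]
            key = (a.residue_index, a.residue_name)
            if key != prev_key:
                groups.append([])
                prev_key = key
            groups[-1].append(i)
        for group in groups:
            first = model.atoms[group[0]]
            res = gemmi.Residue()
            res.name = first.residue_name
            res.seqid = gemmi.SeqId(first.residue_index, " ")
            res.het_flag = "H" if group[0] in het else "A"
            for i in group:
                a = model.atoms[i]
                at = gemmi.Atom()
                at.name = a.atom_name
                at.element = gemmi.Element(a.element)
                at.pos = gemmi.Position(*a.position)
                at.b_iso = a.b_factor
                at.occ = 1.0
                res.add_atom(at)
            chain.add_residue(res)
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    with open(path, "w") as fh:
        fh.write(st.make_pdb_string())


def _kabsch(mob: np.ndarray, ref: np.ndarray) -> tuple[RigidTransform, float]:
    cm, cr = mob.mean(axis=0), ref.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - cr, mob - cm)
    R = rot.as_matrix()
    t = cr - R @ cm
    moved = mob @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return RigidTransform(R, t), rmsd


def superpose_kabsch(
    mobile: AtomicModel,
    reference: AtomicModel,
    pairing: list[tuple[int, int]],
) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of paired atoms (Kabsch).

    ``pairing`` lists (mobile atom index, reference atom index). Returns the
    transform minimizing RMSD over the pairing and that minimal RMSD.
    """
    if len(pairing) < 3:
        raise DegenerateInputError("superposition needs at least 3 pairs")
    mi = [p[0] for p in pairing]
    ri = [p[1] for p in pairing]
    mob = mobile.coords[mi]
    ref = reference.coords[ri]
    for pts in (mob, ref):
        centered = pts - pts.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
            raise DegenerateInputError("paired points are collinear")
    return _kabsch(mob, ref)


def tm_score(
    model: AtomicModel,
    reference: AtomicModel,
    pairing: list[tuple[int, int]],
) -> float:
    """Length-normalized structure similarity in (0, 1].

    TM = max over superpositions of (1/L_ref) sum 1/(1 + (d_i/d0)^2) with
    d0 = 1.24 (L_ref - 15)^(1/3) - 1.8.  The maximization uses the standard
    heuristic: Kabsch seeded from contiguous fragments, then iterated on the
    subset of pairs closer than 2 d0.  Exact for identical and rigidly moved
    copies; a lower bound in general.
    """
    L = len(pairing)
    if L < 16:
        raise ValueError("TM-score needs at least 16 paired residues")
    d0 = 1.24 * (L - 15) ** (1.0 / 3.0) - 1.8
    mob = model.coords[[p[0] for p in pairing]]
    ref = reference.coords[[p[1] for p in pairing]]

    def score_of(R: np.ndarray, t: np.ndarray) -> float:
        d = np.linalg.norm(mob @ R.T + t - ref, axis=1)
        return float(np.mean(1.0 / (1.0 + (d / d0) ** 2)))

    seeds = [np.arange(L)]
    for frag in (L // 2, max(L // 4, 8)):
        if frag < 3:
            continue
        for start in range(0, L - frag + 1, max(frag // 2, 1)):
            seeds.append(np.arange(start, start + frag))

    best = 0.0
    for seed in seeds:
        sub = seed
        for _ in range(30):
            try:
                tr, _ = _kabsch(mob[sub], ref[sub])
            except Exception:
                break
            best = max(best, score_of(tr.rotation, tr.translation))
            d = np.linalg.norm(mob @ tr.rotation.T + tr.translation - ref,
                               axis=1)
            new_sub = np.nonzero(d < 2.0 * d0)[0]
            if len(new_sub) < 3 or np.array_equal(new_sub, sub):
                break
            sub = new_sub
    return best
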