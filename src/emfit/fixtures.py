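"""Synthetic structures, decoys, MSAs and noisy maps for desk-scale runs.

All generators are deterministic for a fixed seed.  Structures are ideal
C-alpha traces: 3.8 A between consecutive residues, helices with 1.5 A
rise and 100 degrees twist per residue.  These are idealized (no side
chains, no library fragments), which is sufficient for density simulation
and fitting at sigma >= 4 A where side-chain detail is unresolved anyway.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from emfit.density import DensityMap
from emfit.errors import ConfigError
from emfit.structures import Atom, AtomicModel, RigidTransform

__all__ = [
    "FixtureSpec", "make_structure", "perturb", "sample_msa",
    "make_noisy_map", "make_decoy_set", "HELIX_RISE", "HELIX_TWIST_DEG",
    "CA_DISTANCE",
]

CA_DISTANCE = 3.8      # A between consecutive C-alpha
HELIX_RISE = 1.5       # A rise per residue
HELIX_TWIST_DEG = 100.0

# radius making consecutive C-alpha distance exactly 3.8 A
_HELIX_RADIUS = math.sqrt(CA_DISTANCE**2 - HELIX_RISE**2) / (
    2.0 * math.sin(math.radians(HELIX_TWIST_DEG / 2.0)))

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class FixtureSpec:
    """Recipe for a toy structure.

    kind: helix | three-helix-bundle | c2-dimer | two-domain-hinge.
    perturbation: optional dict understood by :func:`perturb`, applied
        after construction with the same seed.
    """

    kind: str
    n_residues: int = 30
    seed: int = 0
    perturbation: dict | None = None

    def __post_init__(self):
        if self.n_residues < 10:
            raise ConfigError("fixtures need n_residues >= 10")


def _helix_points(n: int) -> np.ndarray:
    i = np.arange(n)
    ang = np.radians(HELIX_TWIST_DEG) * i
    return np.stack([_HELIX_RADIUS * np.cos(ang),
                     _HELIX_RADIUS * np.sin(ang),
                     HELIX_RISE * i], axis=1)


def _trace(points: np.ndarray, chain_id: str, first_res: int = 1) -> list[Atom]:
    return [Atom(chain_id, first_res + i, "ALA", "CA", "C", tuple(p))
            for i, p in enumerate(points)]


def make_structure(spec: FixtureSpec) -> AtomicModel:
    """Build an ideal C-alpha fixture; deterministic per seed.

    Multi-helix kinds place each helix in its own chain; the
    ``two-domain-hinge`` kind is a single continuous chain whose two halves
    act as rigid domains under :func:`perturb`'s hinge mode.
    """
    n = spec.n_residues
    if spec.kind == "helix":
        atoms = _trace(_helix_points(n), "A")
    elif spec.kind == "two-domain-hinge":
        atoms = _trace(_helix_points(n), "A")
    elif spec.kind == "three-helix-bundle":
        # unequal helix lengths and staggered offsets: the bundle has no
        # approximate self-symmetry, so docking it has a unique optimum
        # even at resolutions where single helices look like plain tubes
        per = [n // 2, n // 3, n - n // 2 - n // 3]
        sep = 8.0
        centers = [np.array([sep, 0.0, 0.0]),
                   np.array([-sep / 2, sep * math.sqrt(3) / 2, 2.0]),
                   np.array([-sep / 2, -sep * math.sqrt(3) / 2, 5.0])]
        atoms = []
        for idx, (cnt, ctr) in enumerate(zip(per, centers)):
            pts = _helix_points(cnt)
            if idx % 2 == 1:  # antiparallel packing
                flip = Rotation.from_euler("x", 180, degrees=True).as_matrix()
                pts = pts @ flip.T
                pts[:, 2] -= pts[:, 2].min()
            atoms += _trace(pts + ctr, "ABC"[idx])
    elif spec.kind == "c2-dimer":
        half = n // 2
        pts = _helix_points(half)
        tilt = Rotation.from_euler("y", 20, degrees=True).as_matrix()
        pts = pts @ tilt.T + np.array([7.0, 0.0, 0.0])
        c2 = Rotation.from_euler("z", 180, degrees=True).as_matrix()
        atoms = _trace(pts, "A") + _trace(pts @ c2.T, "B")
    else:
        raise ConfigError(f"unknown fixture kind {spec.kind!r}")
    model = AtomicModel(atoms, {"kind": spec.kind, "seed": spec.seed})
    if spec.perturbation is not None:
        model = perturb(model, spec.perturbation, spec.seed)
    return model


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def perturb(model: AtomicModel, perturbation: dict, seed: int = 0) -> AtomicModel:
    """Apply a deterministic perturbation; RMSD to the input is recorded in
    ``metadata["perturb_rmsd"]``.

    Kinds (``perturbation["type"]``):
      hinge:  rotate the second half of the atom list by ``angle_deg``
              about the central bond axis (pivot at the bond midpoint);
              the two bond endpoints stay fixed, so hinging by -angle
              restores the input exactly.
      jitter: seeded isotropic Gaussian displacement, ``sd`` A/component.
      rigid:  rotation ``rotvec_deg`` (axis-angle vector, degrees) about
              the centroid plus ``translation``.
    """
    kind = perturbation.get("type")
    coords = model.coords
    if kind == "hinge":
        if len(coords) < 4:
            raise ConfigError("hinge perturbation needs >= 4 atoms")
        angle = float(perturbation["angle_deg"])
        mid = len(coords) // 2
        axis = coords[mid] - coords[mid - 1]
        axis = axis / np.linalg.norm(axis)
        pivot = 0.5 * (coords[mid] + coords[mid - 1])
        R = Rotation.from_rotvec(np.radians(angle) * axis).as_matrix()
        new = coords.copy()
        new[mid:] = (coords[mid:] - pivot) @ R.T + pivot
    elif kind == "jitter":
        sd = float(perturbation["sd"])
        rng = np.random.default_rng(seed)
        new = coords + rng.normal(0.0, sd, size=coords.shape)
    elif kind == "rigid":
        rotvec = np.radians(np.asarray(perturbation.get("rotvec_deg",
                                                        (0, 0, 0)), float))
        trans = np.asarray(perturbation.get("translation", (0, 0, 0)), float)
        R = Rotation.from_rotvec(rotvec).as_matrix()
        ctr = coords.mean(axis=0)
        new = (coords - ctr) @ R.T + ctr + trans
    else:
        raise ConfigError(f"unknown perturbation type {kind!r}")
    out = model.with_coords(new)
    out.metadata["perturb_rmsd"] = _rmsd(coords, new)
    out.metadata["perturbation"] = dict(perturbation)
    return out


def sample_msa(
    query: str,
    n_sequences: int,
    substitution_rate: float,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Sample an aligned MSA around a query sequence.

    Each non-query sequence mutates every position independently with
    probability ``substitution_rate``; a mutated letter is drawn uniformly
    from the 20 amino acids (self-substitution allowed, so the expected
    query-letter frequency at rate 1 is 1/20).  Record 1 is the intact
    query.  Returns (label, sequence) pairs of equal length.
    """
    if not 0.0 <= substitution_rate <= 1.0:
        raise ConfigError("substitution_rate must be in [0, 1]")
    query = query.upper()
    if any(c not in AMINO_ACIDS for c in query):
        raise ConfigError("query must use the 20 standard amino-acid letters")
    rng = np.random.default_rng(seed)
    letters = np.array(list(AMINO_ACIDS))
    qarr = np.array(list(query))
    records = [("query", query)]
    for s in range(1, n_sequences):
        mutate = rng.random(len(query)) < substitution_rate
        draw = letters[rng.integers(0, 20, size=len(query))]
        seq = np.where(mutate, draw, qarr)
        records.append((f"seq{s}", "".join(seq)))
    return records


def make_noisy_map(
    dmap: DensityMap,
    noise_sd: float,
    seed: int = 0,
    clamp_negative: bool = False,
) -> DensityMap:
    """Add seeded white Gaussian noise with sd ``noise_sd * max(map)``."""
    if noise_sd < 0:
        raise ConfigError("noise_sd must be >= 0")
    out = dmap.copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sd = noise_sd * float(np.max(np.abs(dmap.values)))
        out.values = out.values + rng.normal(0.0, sd, size=dmap.dims)
        if clamp_negative:
            np.clip(out.values, 0.0, None, out=out.values)
    out.metadata["noise_sd"] = noise_sd
    out.metadata["noise_seed"] = seed
    return out


def make_decoy_set(
    reference: AtomicModel,
    n_decoys: int = 10,
    seed: int = 0,
) -> list[tuple[str, AtomicModel]]:
    """Decoy library: one near-native model plus increasingly distorted ones.

    Decoy 0 ("near_native") carries 0.2 A jitter; decoy i >= 1 carries
    jitter of 1 + 0.5 i A, so quality decays monotonically in expectation.
    """
    out = [("near_native", perturb(reference, {"type": "jitter", "sd": 0.2},
                                   seed))]
    for i in range(1, n_decoys):
        out.append((f"decoy{i:02d}",
                    perturb(reference, {"type": "jitter", "sd": 1.0 + 0.5 * i},
                            seed + i)))
    return out
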