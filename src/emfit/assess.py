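"""Map-model agreement metrics: CCmask, CCvolume, CCpeaks, CCbox and SMOC.

The four CC metrics are centered Pearson correlations between the
experimental map and the model's simulated map over different voxel
selections:

  CCmask   -- voxels within a fixed radius of any model atom;
  CCvolume -- the v highest-valued voxels of the MODEL map, v being the
              CCmask mask size (compares the molecular envelope);
  CCpeaks  -- the union of the v highest voxels of the model map and the
              v highest of the experimental map (strongest features);
  CCbox    -- every voxel of the grid.

SMOC is the per-residue segment-based Manders overlap coefficient: for a
sliding window of residues, the NON-centered overlap
sum(e s) / sqrt(sum e^2 sum s^2) over voxels near the segment's atoms.
The coexistence of centered (Pearson) and non-centered (Manders)
conventions follows the metrics' respective source definitions and is
deliberate.  The mask here is a union of fixed-radius spheres around
atoms, not per-element atomic radii.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.spatial import cKDTree

from emfit.density import DensityMap, DensitySimParams, simulate_density, zone_mask
from emfit.errors import ConfigError, DegenerateInputError
from emfit.structures import AtomicModel

__all__ = [
    "MapModelScores", "SmocProfile", "SmocEntry",
    "cc_mask", "cc_volume", "cc_peaks", "cc_box", "cc_suite", "smoc",
]


@dataclass(frozen=True)
class MapModelScores:
    """The four whole-model CC metrics plus the mask size they share."""

    cc_mask: float
    cc_volume: float
    cc_peaks: float
    cc_box: float
    mask_voxels: int


class SmocEntry(NamedTuple):
    chain_id: str
    residue_index: int
    smoc: float  # NaN when the residue's mask is empty


@dataclass
class SmocProfile:
    """Per-residue SMOC values with the window/radius used to compute them."""

    entries: list[SmocEntry]
    window: int
    radius: float

    def values(self) -> np.ndarray:
        return np.array([e.smoc for e in self.entries])

    def minimum(self) -> SmocEntry:
        finite = [e for e in self.entries if math.isfinite(e.smoc)]
        return min(finite, key=lambda e: e.smoc)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    da = a - a.mean()
    db = b - b.mean()
    na, nb = float(np.dot(da, da)), float(np.dot(db, db))
    if na == 0.0 or nb == 0.0:
        raise DegenerateInputError(
            "constant map values in region: correlation undefined")
    return float(np.dot(da, db) / math.sqrt(na * nb))


def _manders(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = float(np.dot(a, a)), float(np.dot(b, b))
    if na == 0.0 or nb == 0.0:
        raise DegenerateInputError("all-zero map values in segment mask")
    return float(np.dot(a, b) / math.sqrt(na * nb))


def _sim_and_mask(exp_map, model, sigma, mask_radius, truncation_radius=4.0):
    params = DensitySimParams(sigma=sigma,
                              truncation_radius=truncation_radius)
    sim = simulate_density(model, grid=exp_map, params=params)
    mask = zone_mask(exp_map, model, mask_radius)
    if not mask.any():
        raise DegenerateInputError("atom mask selects no voxels")
    return sim, mask


def cc_mask(
    exp_map: DensityMap,
    model: AtomicModel,
    sigma: float,
    mask_radius: float = 3.0,
) -> float:
    """Pearson CC over voxels within ``mask_radius`` A of any model atom."""
    sim, mask = _sim_and_mask(exp_map, model, sigma, mask_radius)
    return _pearson(exp_map.values[mask], sim.values[mask])


def _top_indices(values: np.ndarray, v: int) -> np.ndarray:
    flat = values.ravel()
    v = min(v, flat.size)
    return np.argpartition(flat, -v)[-v:]


def cc_volume(
    exp_map: DensityMap,
    model: AtomicModel,
    sigma: float,
    mask_radius: float = 3.0,
) -> float:
    """Pearson CC over the mask-sized set of highest model-map voxels."""
    sim, mask = _sim_and_mask(exp_map, model, sigma, mask_radius)
    idx = _top_indices(sim.values, int(mask.sum()))
    return _pearson(exp_map.values.ravel()[idx], sim.values.ravel()[idx])


def cc_peaks(
    exp_map: DensityMap,
    model: AtomicModel,
    sigma: float,
    mask_radius: float = 3.0,
) -> float:
    """Pearson CC over the union of both maps' highest-valued regions."""
    sim, mask = _sim_and_mask(exp_map, model, sigma, mask_radius)
    v = int(mask.sum())
    idx = np.union1d(_top_indices(sim.values, v),
                     _top_indices(exp_map.values, v))
    return _pearson(exp_map.values.ravel()[idx], sim.values.ravel()[idx])


def cc_box(exp_map: DensityMap, model: AtomicModel, sigma: float) -> float:
    """Pearson CC over the entire grid (crop to a box upstream if local)."""
    params = DensitySimParams(sigma=sigma)
    sim = simulate_density(model, grid=exp_map, params=params)
    return _pearson(exp_map.values.ravel(), sim.values.ravel())


def cc_suite(
    exp_map: DensityMap,
    model: AtomicModel,
    sigma: float,
    mask_radius: float = 3.0,
) -> MapModelScores:
    """All four CC metrics from one simulated map and one mask."""
    sim, mask = _sim_and_mask(exp_map, model, sigma, mask_radius)
    v = int(mask.sum())
    ev, sv = exp_map.values.ravel(), sim.values.ravel()
    top_sim = _top_indices(sim.values, v)
    union = np.union1d(top_sim, _top_indices(exp_map.values, v))
    return MapModelScores(
        cc_mask=_pearson(exp_map.values[mask], sim.values[mask]),
        cc_volume=_pearson(ev[top_sim], sv[top_sim]),
        cc_peaks=_pearson(ev[union], sv[union]),
        cc_box=_pearson(ev, sv),
        mask_voxels=v,
    )


def smoc(
    exp_map: DensityMap,
    model: AtomicModel,
    sigma: float,
    window: int = 11,
    radius: float = 3.0,
) -> SmocProfile:
    """Per-residue segment-based Manders overlap coefficient.

    For each residue, the segment is ``window`` residues centered on it
    (clipped at chain termini; chains shorter than the window use the whole
    chain), the mask is all voxels within ``radius`` of any segment atom,
    and the score is the non-centered overlap of experimental and simulated
    values over that mask.  Residues whose mask is empty get NaN.
    """
    if window % 2 != 1 or window < 1:
        raise ConfigError("smoc window must be odd and positive")
    params = DensitySimParams(sigma=sigma)
    sim = simulate_density(model, grid=exp_map, params=params)
    centers = exp_map.voxel_centers()
    tree = cKDTree(centers)
    coords = model.coords
    atoms = model.atoms
    half = window // 2
    ev, sv = exp_map.values.ravel(), sim.values.ravel()

    entries: list[SmocEntry] = []
    for cid, sl in model.chain_slices().items():
        # residues in chain order, with their atom indices
        res_order: list[int] = []
        res_atoms: dict[int, list[int]] = {}
        for i in range(sl.start, sl.stop):
            r = atoms[i].residue_index
            if r not in res_atoms:
                res_order.append(r)
                res_atoms[r] = []
            res_atoms[r].append(i)
        nres = len(res_order)
        for pos, r in enumerate(res_order):
            lo = max(0, pos - half)
            hi = min(nres, pos + half + 1)
            seg_atoms = [i for rr in res_order[lo:hi] for i in res_atoms[rr]]
            idx_lists = tree.query_ball_point(coords[seg_atoms], radius)
            vox = sorted({i for lst in idx_lists for i in lst})
            if not vox:
                entries.append(SmocEntry(cid, r, float("nan")))
                continue
            try:
                val = _manders(ev[vox], sv[vox])
            except DegenerateInputError:
                val = float("nan")
            entries.append(SmocEntry(cid, r, val))
    return SmocProfile(entries, window, radius)
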