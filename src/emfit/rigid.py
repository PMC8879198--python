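"""Exhaustive 6-D rigid-body docking of a model into a density map.

The search enumerates rotations on a z-y-z Euler lattice; for each rotation
the centered model's simulated density is cross-correlated against the
experimental map over all integer voxel shifts with an FFT, top peaks are
pooled across rotations by the correlation numerator, the best candidates
are rescored with the exact (scale-invariant) CCC, and finally the top
placements are polished off-lattice by direct CCC maximization -- the same
lattice-search-then-peak-refinement strategy used by FFT docking programs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.signal import fftconvolve
from scipy.spatial.transform import Rotation

from emfit.density import DensityMap, DensitySimParams, ccc, simulate_density
from emfit.errors import ConfigError, GridError, SearchFailureError
from emfit.structures import AtomicModel, RigidTransform

__all__ = [
    "Placement", "RigidSearchConfig", "enumerate_rotations",
    "translation_scan", "rigid_fit",
]


@dataclass(frozen=True)
class Placement:
    """One docking candidate: rigid transform, its exact CCC and rank."""

    transform: RigidTransform
    ccc: float
    rank: int


@dataclass
class RigidSearchConfig:
    """Search parameters.

    angular_step: Euler-lattice step in degrees (0, 90].
    top_k_rescore: lattice candidates rescored with the exact CCC.
    peak_min_separation: minimum voxel distance between translation peaks.
    peaks_per_rotation: peaks kept from each rotation's scan.
    refine_top: placements polished off-lattice (Powell over rotation
        vector + translation); 0 disables refinement.
    include_input_pose: also score the model exactly as given, so the
        returned best is never worse than the starting pose.
    """

    sim_params: DensitySimParams
    angular_step: float = 20.0
    top_k_rescore: int = 20
    peak_min_separation: int = 2
    peaks_per_rotation: int = 3
    refine_top: int = 3
    include_input_pose: bool = True

    def __post_init__(self):
        if not 0 < self.angular_step <= 90:
            raise ConfigError("angular_step must be in (0, 90] degrees")
        if self.top_k_rescore < 1:
            raise ConfigError("top_k_rescore must be >= 1")


def enumerate_rotations(angular_step: float) -> list[RigidTransform]:
    """Deterministic covering of SO(3) by a z-y-z Euler lattice.

    The polar rows (beta = 0, 180) keep gamma = 0 only, since alpha and
    gamma are degenerate there.  The identity is always included.
    """
    if not 0 < angular_step <= 90:
        raise ConfigError("angular_step must be in (0, 90] degrees")
    step = float(angular_step)
    alphas = np.arange(0.0, 360.0 - 1e-9, step)
    betas = np.arange(0.0, 180.0 + 1e-9, step)
    out = []
    for b in betas:
        polar = b < 1e-9 or b > 180.0 - 1e-9
        for a in alphas:
            gammas = (0.0,) if polar else np.arange(0.0, 360.0 - 1e-9, step)
            for g in gammas:
                R = Rotation.from_euler("zyz", [a, b, g],
                                        degrees=True).as_matrix()
                out.append(RigidTransform(R, np.zeros(3)))
    return out


def translation_scan(
    exp_map: DensityMap, sim_map: DensityMap,
) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Correlation numerator for every integer voxel shift (FFT).

    scores[s] = sum_v exp[s + v] * sim[v] for all shifts keeping the
    simulated map inside the experimental grid.  The best shift is the
    argmax; ties break by smallest shift norm, then lexicographically.
    """
    if not np.allclose(exp_map.spacing, sim_map.spacing, atol=1e-6):
        raise GridError("translation scan requires equal voxel spacing")
    if any(ds > de for ds, de in zip(sim_map.dims, exp_map.dims)):
        raise GridError("simulated map does not fit inside experimental map")
    kernel = sim_map.values[::-1, ::-1, ::-1]
    scores = fftconvolve(exp_map.values, kernel, mode="valid")
    smax = scores.max()
    cand = np.argwhere(np.isclose(scores, smax, rtol=1e-9, atol=0.0))
    key = np.sum(cand**2, axis=1)
    order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0], key))
    best = tuple(int(c) for c in cand[order[0]])
    return scores, best


def _extract_peaks(scores: np.ndarray, n_peaks: int, min_sep: int):
    """Greedy non-maximum suppression: top values at >= min_sep voxels."""
    flat = scores.ravel()
    n_top = min(flat.size, max(20 * n_peaks, n_peaks))
    idx = np.argpartition(flat, -n_top)[-n_top:]
    idx = idx[np.argsort(flat[idx])[::-1]]
    shifts = np.stack(np.unravel_index(idx, scores.shape), axis=1)
    kept: list[tuple[float, tuple[int, int, int]]] = []
    for row, i in zip(shifts, idx):
        if all(np.sum((row - np.array(s)) ** 2) >= min_sep**2
               for _, s in kept):
            kept.append((float(flat[i]), tuple(int(v) for v in row)))
            if len(kept) >= n_peaks:
                break
    return kept


def _sim_grid_for(coords: np.ndarray, exp_map: DensityMap,
                  params: DensitySimParams) -> DensityMap:
    pad = params.truncation_radius * params.sigma
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    dims = np.ceil((hi - lo) / exp_map.spacing).astype(int) + 1
    dims = np.minimum(dims, exp_map.dims)  # must fit for the valid scan
    return DensityMap(np.zeros(dims), lo, exp_map.spacing.copy())


def _exact_ccc(exp_map: DensityMap, model: AtomicModel,
               transform: RigidTransform, params: DensitySimParams) -> float:
    placed = model.transformed(transform)
    sim = simulate_density(placed, grid=exp_map, params=params)
    if not np.any(sim.values):
        return float("-inf")
    return ccc(exp_map, sim)


def _refine_placement(exp_map, model, transform, params) -> RigidTransform:
    """Polish a placement off-lattice: Powell over a local rotation-vector
    increment (about the placed centroid) and a translation increment."""
    centroid = model.coords.mean(axis=0)
    placed_ctr = transform.apply(centroid[None, :])[0]

    def with_delta(p: np.ndarray) -> RigidTransform:
        Rd = Rotation.from_rotvec(p[:3]).as_matrix()
        delta = RigidTransform(Rd, placed_ctr - Rd @ placed_ctr + p[3:])
        return delta.compose(transform)

    def objective(p: np.ndarray) -> float:
        try:
            return -_exact_ccc(exp_map, model, with_delta(p), params)
        except Exception:
            return 0.0

    span = float(np.max(exp_map.spacing))
    res = minimize(objective, np.zeros(6), method="Powell",
                   options={"xtol": 1e-3, "ftol": 1e-6, "maxfev": 400},
                   bounds=[(-0.6, 0.6)] * 3 + [(-2 * span, 2 * span)] * 3)
    return with_delta(res.x)


def rigid_fit(
    exp_map: DensityMap,
    model: AtomicModel,
    config: RigidSearchConfig,
) -> list[Placement]:
    """Dock a model into a map; returns placements ranked by exact CCC.

    The model is centered at its centroid before rotation; the returned
    transforms act on the model's original coordinates.
    """
    params = config.sim_params
    centroid = model.coords.mean(axis=0)
    centered = model.coords - centroid
    rotations = enumerate_rotations(config.angular_step)

    pool: list[tuple[float, RigidTransform]] = []
    for rot in rotations:
        rc = centered @ rot.rotation.T
        grid = _sim_grid_for(rc, exp_map, params)
        sim = simulate_density(model.with_coords(rc), grid=grid,
                               params=params)
        scores, _ = translation_scan(exp_map, sim)
        for num, shift in _extract_peaks(scores, config.peaks_per_rotation,
                                         config.peak_min_separation):
            delta = (exp_map.origin + np.array(shift) * exp_map.spacing
                     - grid.origin)
            transform = RigidTransform(rot.rotation,
                                       delta - rot.rotation @ centroid)
            pool.append((num, transform))
    if not pool:
        raise SearchFailureError("translation scans produced no peaks")

    pool.sort(key=lambda x: -x[0])
    candidates = [t for _, t in pool[:config.top_k_rescore]]
    if config.include_input_pose:
        candidates.append(RigidTransform.identity())

    scored: list[tuple[float, RigidTransform]] = []
    for t in candidates:
        try:
            scored.append((_exact_ccc(exp_map, model, t, params), t))
        except Exception:
            continue
    scored = [(c, t) for c, t in scored if math.isfinite(c)]
    if not scored:
        raise SearchFailureError("no candidate with a finite CCC")
    scored.sort(key=lambda x: -x[0])

    if config.refine_top > 0:
        refined = []
        for c, t in scored[:config.refine_top]:
            t2 = _refine_placement(exp_map, model, t, params)
            c2 = _exact_ccc(exp_map, model, t2, params)
            refined.append((c2, t2) if c2 > c else (c, t))
        scored = refined + scored[config.refine_top:]
        scored.sort(key=lambda x: -x[0])

    return [Placement(t, c, rank) for rank, (c, t) in enumerate(scored, 1)]
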