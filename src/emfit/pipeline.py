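"""Candidate selection layer: dock-and-score tables, threshold filtering,
secondary-structure similarity, and subunit assembly with clash checks.

Candidate tables are plain pandas DataFrames (one row per model, column
``model_id`` unique) so external quality scores computed elsewhere
(VERIFY3D, dDFIRE, alignment Z-scores, ...) can be merged in as ordinary
columns and used in filters; this package computes only the map-fit and
secondary-structure columns itself.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from emfit.density import DensityMap, DensitySimParams
from emfit.errors import ConfigError, EmfitError, SearchFailureError
from emfit.rigid import RigidSearchConfig, rigid_fit
from emfit.structures import AtomicModel, RigidTransform

__all__ = [
    "FilterSpec", "score_candidates", "filter_candidates",
    "ss_similarity", "assign_ss_from_ca", "assemble",
]

_COMPARATORS = {
    ">": np.greater,
    ">=": np.greater_equal,
    "<": np.less,
    "<=": np.less_equal,
}


@dataclass
class FilterSpec:
    """Threshold filter: every (column, comparator, threshold) must hold.

    Comparators: ``>  >=  <  <=``.  ``rank_key`` orders the output
    (descending), ties broken by model_id.
    """

    criteria: list[tuple[str, str, float]] = field(default_factory=list)
    rank_key: str = "ccc"

    def __post_init__(self):
        for name, cmp, _ in self.criteria:
            if cmp not in _COMPARATORS:
                raise ConfigError(f"unknown comparator {cmp!r} for {name!r}")


def _as_labelled(models) -> list[tuple[str, AtomicModel]]:
    out = []
    for i, m in enumerate(models):
        if isinstance(m, tuple):
            out.append((str(m[0]), m[1]))
        else:
            out.append((m.metadata.get("model_id", f"model_{i:03d}"), m))
    if len({mid for mid, _ in out}) != len(out):
        raise ConfigError("model_id values must be unique")
    return out


def score_candidates(
    models,
    exp_map: DensityMap,
    sim_params: DensitySimParams,
    search_config: RigidSearchConfig | None = None,
) -> pd.DataFrame:
    """Rigid-dock every model into the map and tabulate the best CCC.

    ``models`` is a list of AtomicModel or (model_id, AtomicModel) pairs.
    Models whose docking fails are kept with ``fit_failed = True`` and a
    NaN ccc.  Rows are ordered by model_id; the winning placements are
    stashed in ``df.attrs["placements"]`` (model_id -> Placement).
    """
    if search_config is None:
        search_config = RigidSearchConfig(sim_params=sim_params)
    labelled = sorted(_as_labelled(models), key=lambda t: t[0])
    if not labelled:
        raise ConfigError("score_candidates needs at least one model")
    rows, placements = [], {}
    for mid, model in labelled:
        try:
            placed = rigid_fit(exp_map, model, search_config)
            best = placed[0]
            rows.append({"model_id": mid, "ccc": best.ccc,
                         "fit_failed": False})
            placements[mid] = best
        except (SearchFailureError, EmfitError) as exc:
            warnings.warn(f"rigid fit failed for {mid}: {exc}")
            rows.append({"model_id": mid, "ccc": float("nan"),
                         "fit_failed": True})
    df = pd.DataFrame(rows)
    df.attrs["placements"] = placements
    return df


def filter_candidates(table: pd.DataFrame, spec: FilterSpec) -> pd.DataFrame:
    """Mark records passing ALL thresholds; sort by the rank key.

    Returns a copy with a boolean ``selected`` column, sorted by
    ``spec.rank_key`` descending (ties by model_id).  Idempotent.
    """
    for name, _, _ in spec.criteria:
        if name not in table.columns:
            raise ConfigError(f"filter references unknown column {name!r}")
    if spec.rank_key not in table.columns:
        raise ConfigError(f"rank key {spec.rank_key!r} not in table")
    out = table.copy()
    mask = pd.Series(True, index=out.index)
    for name, cmp, threshold in spec.criteria:
        col = out[name].astype(float)
        mask &= _COMPARATORS[cmp](col, threshold) & col.notna()
    out["selected"] = mask
    if not mask.any():
        warnings.warn("no candidate passes the filter thresholds")
    out = out.sort_values([spec.rank_key, "model_id"],
                          ascending=[False, True],
                          kind="mergesort").reset_index(drop=True)
    out.attrs = dict(table.attrs)
    return out


def ss_similarity(ss_model: str, ss_predicted: str) -> float:
    """Fraction of positions with the same H/E/C state."""
    if len(ss_model) != len(ss_predicted):
        raise ValueError("secondary-structure strings differ in length")
    if not ss_model:
        raise ValueError("empty secondary-structure strings")
    same = sum(a == b for a, b in zip(ss_model, ss_predicted))
    return same / len(ss_model)


# C-alpha distance bands (A) for geometric secondary-structure assignment,
# P-SEA-style.  An ideal alpha-helix has d(i,i+3) ~ 5.0 and d(i,i+4) ~ 6.2;
# extended strands have d(i,i+2) ~ 6.7-7.6.
HELIX_D13 = (4.2, 5.8)
HELIX_D14 = (4.9, 6.9)
STRAND_D12 = (6.4, 7.7)


def assign_ss_from_ca(model: AtomicModel) -> str:
    """Assign H/E/C per residue from C-alpha geometry alone.

    A residue window starting at i is helical when both d(i,i+3) and
    d(i,i+4) fall in the helical bands (residues i..i+4 marked H);
    strand when d(i,i+2) is in the extended band (i..i+2 marked E, unless
    already H); otherwise coil.  Chains under 5 residues are all coil.
    Returns one letter per C-alpha, concatenated over chains in atom order.
    """
    out = []
    coords = model.coords
    for cid, sl in model.chain_slices().items():
        ca = [i for i in range(sl.start, sl.stop)
              if model.atoms[i].atom_name == "CA"]
        n = len(ca)
        ss = ["C"] * n
        if n >= 5:
            pts = coords[ca]
            d = lambda i, j: float(np.linalg.norm(pts[i] - pts[j]))
            for i in range(n - 4):
                d13, d14 = d(i, i + 3), d(i, i + 4)
                if HELIX_D13[0] <= d13 <= HELIX_D13[1] and \
                        HELIX_D14[0] <= d14 <= HELIX_D14[1]:
                    for j in range(i, i + 5):
                        ss[j] = "H"
            for i in range(n - 2):
                if ss[i] == "H" or ss[i + 2] == "H":
                    continue
                if STRAND_D12[0] <= d(i, i + 2) <= STRAND_D12[1]:
                    for j in range(i, i + 3):
                        if ss[j] != "H":
                            ss[j] = "E"
        out.append("".join(ss))
    return "".join(out)


_CHAIN_LABELS = string.ascii_uppercase + string.ascii_lowercase + string.digits


def assemble(
    placed: list[tuple[AtomicModel, RigidTransform]],
    clash_cutoff: float = 3.0,
) -> tuple[AtomicModel, dict]:
    """Apply placements, relabel chains uniquely, report inter-component
    C-alpha pairs closer than ``clash_cutoff``.

    Returns (assembly, report); report has ``clash_count`` and ``pairs``
    (component i, atom i, component j, atom j, distance).
    """
    from scipy.spatial import cKDTree

    if len(placed) < 2:
        raise ConfigError("assembly needs at least 2 components")
    atoms = []
    comp_ca: list[tuple[int, np.ndarray, np.ndarray]] = []
    label_iter = iter(_CHAIN_LABELS)
    for ci, (model, transform) in enumerate(placed):
        moved = model.transformed(transform)
        relabel = {}
        for cid in moved.chain_ids:
            try:
                relabel[cid] = next(label_iter)
            except StopIteration:
                raise EmfitError("more than 62 chains: cannot relabel")
        from dataclasses import replace as _replace
        atoms += [_replace(a, chain_id=relabel[a.chain_id])
                  for a in moved.atoms]
        ca = moved.ca_indices()
        comp_ca.append((ci, ca, moved.coords[ca]))

    pairs = []
    for i in range(len(comp_ca)):
        _, ca_i, pts_i = comp_ca[i]
        tree = cKDTree(pts_i)
        for j in range(i + 1, len(comp_ca)):
            _, ca_j, pts_j = comp_ca[j]
            for bj, hits in enumerate(tree.query_ball_point(pts_j,
                                                            clash_cutoff)):
                for ai in hits:
                    dist = float(np.linalg.norm(pts_i[ai] - pts_j[bj]))
                    pairs.append((i, int(ca_i[ai]), j, int(ca_j[bj]), dist))
    report = {"clash_count": len(pairs), "pairs": pairs,
              "clash_cutoff": clash_cutoff}
    return AtomicModel(atoms, {"n_components": len(placed)}), report
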