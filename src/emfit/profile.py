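"""Sequence profiles and profile-profile alignment.

A profile is an L x 20 matrix of position-specific scores (log-odds against
a uniform background here).  Two profiles are aligned by affine-gap dynamic
programming where the match score of a position pair is the Pearson
correlation of the two 20-dimensional columns, and alignment raw scores are
standardized into Z-scores after regressing out log(length product) across
a template library.

Alignment modes
---------------
``glocal`` (default): global alignment with free end gaps -- the path must
span one of the sequences at each end (leading/trailing overhang of the
other is free), and every internal position is paid for.  This is the mode
used for template detection, where the query region should be covered.
``local``: Smith-Waterman; the single best-scoring contiguous region.

A gap run of length g costs ``gap_open + gap_extend * (g - 1)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from emfit.errors import ConfigError, DegenerateInputError, FormatError

__all__ = [
    "AA_ORDER", "SequenceProfile", "ProfileAlignment", "ZScoreCalibration",
    "build_profile_from_msa", "column_score", "align_profiles",
    "alignment_score", "calibrate_zscores", "zscore", "split_query",
    "read_msa_fasta",
]

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}
_GAP_CHARS = set("-.")


@dataclass
class SequenceProfile:
    """Consensus sequence plus an L x 20 position-specific score matrix."""

    sequence: str
    columns: np.ndarray
    label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.columns = np.asarray(self.columns, dtype=float)
        if self.columns.ndim != 2 or self.columns.shape[1] != 20:
            raise ValueError("profile columns must be an L x 20 matrix")
        if len(self.sequence) != self.columns.shape[0]:
            raise ValueError("sequence length != number of columns")
        if self.length < 1:
            raise ValueError("profile must have length >= 1")
        if np.any(self.columns.std(axis=1) == 0.0):
            raise DegenerateInputError(
                "profile has a zero-variance column (correlation undefined)")

    @property
    def length(self) -> int:
        return self.columns.shape[0]

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.columns, columns=list(AA_ORDER))
        df.insert(0, "residue", list(self.sequence))
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, label: str = "") -> "SequenceProfile":
        df = pd.read_csv(path, sep="\t")
        seq = "".join(df["residue"].astype(str))
        return cls(seq, df[list(AA_ORDER)].to_numpy(float), label=label)


@dataclass
class ProfileAlignment:
    """Monotone position pairing with its raw score and optional Z-score."""

    pairs: list[tuple[int, int]]
    raw_score: float
    query_label: str = ""
    template_label: str = ""
    z_score: float | None = None
    gap_open: float = 1.0
    gap_extend: float = 0.1
    mode: str = "glocal"

    def __post_init__(self):
        q = [p[0] for p in self.pairs]
        t = [p[1] for p in self.pairs]
        if any(b <= a for a, b in zip(q, q[1:])) or \
           any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("alignment pairs must be strictly increasing")


@dataclass
class ZScoreCalibration:
    """Linear model of raw score vs log(Lq * Lt) plus residual spread."""

    slope: float
    intercept: float
    residual_sd: float
    n_points: int

    def __post_init__(self):
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")
        if self.n_points < 10:
            raise ValueError("calibration needs >= 10 points")

    def expected(self, lq: int, lt: int) -> float:
        return self.intercept + self.slope * math.log(lq * lt)


def read_msa_fasta(path) -> list[tuple[str, str]]:
    """Read an aligned FASTA file into (label, sequence) pairs."""
    from Bio import SeqIO

    records = [(r.id, str(r.seq).upper())
               for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def build_profile_from_msa(
    msa, pseudocount: float = 1.0, label: str = "",
) -> SequenceProfile:
    """Build a log-odds profile from an aligned MSA.

    ``msa`` is a list of (label, sequence) pairs or a FASTA path; the first
    record is the query, and columns where the query has a gap are dropped.
    The additive pseudocount acts on relative frequencies,
    f_a = (count_a / n_nongap + pc) / (1 + 20 pc), so duplicating every
    sequence leaves the profile unchanged; the stored score is
    log(f_a * 20) (log-odds against the uniform background 1/20).
    """
    if pseudocount < 0:
        raise ConfigError("pseudocount must be >= 0")
    if isinstance(msa, (str, bytes)) or hasattr(msa, "read"):
        msa = read_msa_fasta(msa)
    seqs = [s.upper() for _, s in msa]
    L_all = len(seqs[0])
    if any(len(s) != L_all for s in seqs):
        raise FormatError("ragged MSA: records have unequal lengths")
    query = seqs[0]
    keep = [c for c in range(L_all) if query[c] not in _GAP_CHARS]
    cols = np.zeros((len(keep), 20))
    for out_c, c in enumerate(keep):
        counts = np.zeros(20)
        n = 0
        for s in seqs:
            ch = s[c]
            if ch in _GAP_CHARS:
                continue
            if ch not in _AA_INDEX:
                continue  # unknown letters (X etc.) excluded from counts
            counts[_AA_INDEX[ch]] += 1
            n += 1
        if n == 0:
            warnings.warn(f"column {c} has only gaps; dropped")
            continue
        freq = (counts / n + pseudocount) / (1.0 + 20.0 * pseudocount)
        cols[out_c] = np.log(np.maximum(freq, 1e-12) * 20.0)
    seq = "".join(query[c] for c in keep)
    return SequenceProfile(seq, cols, label=label,
                           metadata={"n_sequences": len(seqs),
                                     "pseudocount": pseudocount})


def column_score(col_a: np.ndarray, col_b: np.ndarray) -> float:
    """Pearson correlation of two 20-dimensional profile columns."""
    a = np.asarray(col_a, float)
    b = np.asarray(col_b, float)
    da = a - a.mean()
    db = b - b.mean()
    na, nb = np.dot(da, da), np.dot(db, db)
    if na == 0.0 or nb == 0.0:
        raise DegenerateInputError("zero-variance column in correlation")
    return float(np.dot(da, db) / math.sqrt(na * nb))


def _score_matrix(query: SequenceProfile, template: SequenceProfile) -> np.ndarray:
    def standardized(cols):
        d = cols - cols.mean(axis=1, keepdims=True)
        norm = np.linalg.norm(d, axis=1, keepdims=True)
        if np.any(norm == 0.0):
            raise DegenerateInputError("zero-variance column in profile")
        return d / norm
    return standardized(query.columns) @ standardized(template.columns).T


_NEG = -1e30


def align_profiles(
    query: SequenceProfile,
    template: SequenceProfile,
    gap_open: float = 1.0,
    gap_extend: float = 0.1,
    mode: str = "glocal",
) -> ProfileAlignment:
    """Affine-gap DP over the column-correlation matrix (Gotoh).

    Ties in the traceback break deterministically: match, then gap in
    template (vertical), then gap in query (horizontal).
    """
    if gap_open <= 0 or gap_extend <= 0:
        raise ConfigError("gap penalties must be positive")
    if mode not in ("glocal", "local"):
        raise ConfigError(f"unknown alignment mode {mode!r}")
    S = _score_matrix(query, template)
    lq, lt = S.shape
    # M: best ending with (i,j) matched; F: gap in template (query advances);
    # E: gap in query (template advances).  1-based DP indices.
    M = np.full((lq + 1, lt + 1), _NEG)
    E = np.full((lq + 1, lt + 1), _NEG)
    F = np.full((lq + 1, lt + 1), _NEG)
    local = mode == "local"
    for i in range(1, lq + 1):
        for j in range(1, lt + 1):
            prev = max(M[i - 1, j - 1], E[i - 1, j - 1], F[i - 1, j - 1])
            if local:
                prev = max(prev, 0.0)
            elif i == 1 or j == 1:
                prev = max(prev, 0.0)  # free leading overhang on one side
            M[i, j] = S[i - 1, j - 1] + prev
            E[i, j] = max(M[i, j - 1] - gap_open, E[i, j - 1] - gap_extend)
            F[i, j] = max(M[i - 1, j] - gap_open, F[i - 1, j] - gap_extend)

    if local:
        best = float(M.max())
        bi, bj = np.unravel_index(int(M.argmax()), M.shape)
    else:
        # free trailing overhang: best match cell on the last row or column
        last = np.full_like(M, _NEG)
        last[lq, 1:] = M[lq, 1:]
        last[1:, lt] = np.maximum(last[1:, lt], M[1:, lt])
        best = float(last.max())
        bi, bj = np.unravel_index(int(last.argmax()), last.shape)

    # traceback from (bi, bj), which is match-ending by construction
    pairs: list[tuple[int, int]] = []
    i, j, state = int(bi), int(bj), "M"
    tol = 1e-12
    while i > 0 and j > 0:
        if state == "M":
            pairs.append((i - 1, j - 1))
            prev_options = (("M", M[i - 1, j - 1]), ("F", F[i - 1, j - 1]),
                            ("E", E[i - 1, j - 1]))
            target = M[i, j] - S[i - 1, j - 1]
            if (local or i == 1 or j == 1) and target <= 0.0 + tol and \
                    all(v < target - tol for _, v in prev_options):
                break  # alignment starts here
            state = next(s for s, v in prev_options if abs(v - target) <= tol)
            i, j = i - 1, j - 1
        elif state == "F":  # gap in template: query position unmatched
            if abs(F[i, j] - (M[i - 1, j] - gap_open)) <= tol:
                state = "M"
            i -= 1
        else:  # E: gap in query
            if abs(E[i, j] - (M[i, j - 1] - gap_open)) <= tol:
                state = "M"
            j -= 1
    pairs.reverse()
    return ProfileAlignment(pairs, best, query.label, template.label,
                            gap_open=gap_open, gap_extend=gap_extend,
                            mode=mode)


def alignment_score(
    query: SequenceProfile,
    template: SequenceProfile,
    pairs: list[tuple[int, int]],
    gap_open: float = 1.0,
    gap_extend: float = 0.1,
) -> float:
    """Recompute the raw score of a pairing: sum of column correlations
    minus affine costs of internal gap runs (end overhangs free)."""
    if not pairs:
        raise ValueError("empty alignment")
    total = sum(column_score(query.columns[qi], template.columns[tj])
                for qi, tj in pairs)

    def gap_cost(g: int) -> float:
        return 0.0 if g == 0 else gap_open + gap_extend * (g - 1)

    for (q1, t1), (q2, t2) in zip(pairs, pairs[1:]):
        total -= gap_cost(q2 - q1 - 1)
        total -= gap_cost(t2 - t1 - 1)
    return float(total)


def calibrate_zscores(hits: list[tuple[float, int, int]]) -> ZScoreCalibration:
    """Least-squares fit of raw score on log(Lq * Lt) over a hit library."""
    if len(hits) < 10:
        raise ConfigError("calibration needs >= 10 hits")
    s = np.array([h[0] for h in hits], float)
    x = np.array([math.log(h[1] * h[2]) for h in hits])
    n = len(hits)
    if np.allclose(x, x[0]):
        warnings.warn("all length products identical; constant calibration")
        slope, intercept = 0.0, float(s.mean())
        dof = n - 1
    else:
        slope, intercept = np.polyfit(x, s, 1)
        dof = n - 2
    resid = s - (intercept + slope * x)
    sd = float(np.sqrt(np.sum(resid**2) / dof))
    return ZScoreCalibration(float(slope), float(intercept),
                             max(sd, 1e-12), n)


def zscore(s: float, lq: int, lt: int, calib: ZScoreCalibration) -> float:
    """Standardized alignment score given the library calibration."""
    return (s - calib.expected(lq, lt)) / calib.residual_sd


def split_query(
    profile: SequenceProfile,
    fragment_length: int,
    overlap: int = 0,
) -> list[SequenceProfile]:
    """Split a profile into overlapping windows covering its full length.

    Windows advance by ``fragment_length - overlap``; the last window is
    anchored at the end so coverage is complete.  Each fragment records its
    start offset in ``metadata["offset"]``.
    """
    if not fragment_length > overlap >= 0:
        raise ConfigError("need fragment_length > overlap >= 0")
    L = profile.length
    if fragment_length >= L:
        frag = SequenceProfile(profile.sequence, profile.columns.copy(),
                               label=profile.label,
                               metadata=dict(profile.metadata))
        frag.metadata["offset"] = 0
        return [frag]
    step = fragment_length - overlap
    offsets = []
    o = 0
    while o + fragment_length <= L:
        offsets.append(o)
        o += step
    if offsets[-1] + fragment_length < L:
        offsets.append(L - fragment_length)
    out = []
    for off in offsets:
        sl = slice(off, off + fragment_length)
        frag = SequenceProfile(profile.sequence[sl],
                               profile.columns[sl].copy(),
                               label=f"{profile.label}[{off}:{sl.stop}]",
                               metadata=dict(profile.metadata))
        frag.metadata["offset"] = off
        out.append(frag)
    return out
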