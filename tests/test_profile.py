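import itertools
import math

import numpy as np
import pytest

from emfit import fixtures as fx
from emfit.errors import ConfigError, DegenerateInputError, FormatError
from emfit.profile import (
    AA_ORDER,
    SequenceProfile,
    align_profiles,
    alignment_score,
    build_profile_from_msa,
    calibrate_zscores,
    column_score,
    split_query,
    zscore,
)


def random_profile(length, seed, label=""):
    rng = np.random.default_rng(seed)
    return SequenceProfile("A" * length, rng.normal(size=(length, 20)),
                           label=label)


def enumerate_alignments(lq, lt):
    """All nonempty strictly monotone pairings of range(lq) x range(lt)."""
    for k in range(1, min(lq, lt) + 1):
        for qs in itertools.combinations(range(lq), k):
            for ts in itertools.combinations(range(lt), k):
                yield list(zip(qs, ts))


def brute_force_best(q, t, gap_open, gap_extend, mode):
    """Exhaustive optimum over monotone pairings.

    glocal requires the pairing to reach a sequence start at the left end
    and a sequence end at the right end (free overhang on the other side);
    local allows any pairing.
    """
    lq, lt = q.length, t.length
    best = -math.inf
    for pairs in enumerate_alignments(lq, lt):
        if mode == "glocal":
            (q0, t0), (q1, t1) = pairs[0], pairs[-1]
            if not (q0 == 0 or t0 == 0):
                continue
            if not (q1 == lq - 1 or t1 == lt - 1):
                continue
        best = max(best, alignment_score(q, t, pairs, gap_open, gap_extend))
    return best


class TestBuildProfile:
    def test_single_sequence_pseudocount_formula(self):
        prof = build_profile_from_msa([("q", "ACD")], pseudocount=1.0)
        assert prof.length == 3
        expected_hit = math.log((1 + 1) / (1 + 20) * 20)
        expected_miss = math.log(1 / (1 + 20) * 20)
        assert prof.columns[0, AA_ORDER.index("A")] == pytest.approx(
            expected_hit)
        assert prof.columns[0, AA_ORDER.index("C")] == pytest.approx(
            expected_miss)

    def test_identical_sequences_same_as_single(self):
        single = build_profile_from_msa([("q", "ACDEFGHIKL")])
        five = build_profile_from_msa([(f"s{i}", "ACDEFGHIKL")
                                       for i in range(5)])
        assert np.allclose(single.columns, five.columns)

    def test_query_gap_columns_dropped(self):
        msa = [("q", "AC-DE"), ("s", "ACWDE"), ("t", "GCWD-")]
        prof = build_profile_from_msa(msa)
        assert prof.length == 4
        assert prof.sequence == "ACDE"

    def test_ragged_msa_rejected(self):
        with pytest.raises(FormatError):
            build_profile_from_msa([("a", "ACD"), ("b", "AC")])


class TestColumnScore:
    def test_extremes_and_textbook_formula(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=20)
        assert column_score(a, a) == pytest.approx(1.0)
        assert column_score(a, -a + 3.7) == pytest.approx(-1.0)

        b = rng.normal(size=20)
        am, bm = a.mean(), b.mean()
        expected = (sum((x - am) * (y - bm) for x, y in zip(a, b))
                    / math.sqrt(sum((x - am) ** 2 for x in a)
                                * sum((y - bm) ** 2 for y in b)))
        assert column_score(a, b) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            column_score(np.ones(20), np.arange(20.0))


class TestAlignProfiles:
    def test_self_alignment_identity(self):
        prof = random_profile(12, seed=1)
        aln = align_profiles(prof, prof)
        assert aln.pairs == [(i, i) for i in range(12)]
        assert aln.raw_score == pytest.approx(12.0, abs=1e-9)

    def test_insertion_produces_single_gap_run(self):
        rng = np.random.default_rng(2)
        cols = rng.normal(size=(10, 20)) * 3
        q = SequenceProfile("A" * 10, cols)
        ins = rng.normal(size=(3, 20))
        t_cols = np.vstack([cols[:5], ins, cols[5:]])
        t = SequenceProfile("A" * 13, t_cols)
        aln = align_profiles(q, t)
        gaps = [(t2 - t1 - 1) for (_, t1), (_, t2)
                in zip(aln.pairs, aln.pairs[1:])]
        assert sum(g > 0 for g in gaps) == 1
        assert max(gaps) == 3
        assert [p[0] for p in aln.pairs] == list(range(10))

    @pytest.mark.parametrize("mode", ["glocal", "local"])
    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_matches_exhaustive_enumeration(self, mode, seed):
        rng = np.random.default_rng(seed)
        q = SequenceProfile("A" * 4, rng.normal(size=(4, 20)))
        t = SequenceProfile("A" * 5, rng.normal(size=(5, 20)))
        aln = align_profiles(q, t, gap_open=0.8, gap_extend=0.3, mode=mode)
        oracle = brute_force_best(q, t, 0.8, 0.3, mode)
        assert aln.raw_score == pytest.approx(oracle, abs=1e-9)

    def test_raw_score_matches_recomputation(self):
        q = random_profile(15, seed=6)
        t = random_profile(18, seed=7)
        for mode in ("glocal", "local"):
            aln = align_profiles(q, t, mode=mode)
            recomputed = alignment_score(q, t, aln.pairs,
                                         aln.gap_open, aln.gap_extend)
            assert aln.raw_score == pytest.approx(recomputed, abs=1e-9)

    def test_glocal_symmetric_under_swap(self):
        q = random_profile(10, seed=8)
        t = random_profile(14, seed=9)
        s1 = align_profiles(q, t).raw_score
        s2 = align_profiles(t, q).raw_score
        assert s1 == pytest.approx(s2, abs=1e-9)

    def test_dp_dominates_random_alignments(self):
        q = random_profile(8, seed=10)
        t = random_profile(9, seed=11)
        best = align_profiles(q, t, mode="local").raw_score
        rng = np.random.default_rng(12)
        for _ in range(100):
            k = int(rng.integers(1, 8))
            qs = sorted(rng.choice(8, size=k, replace=False))
            ts = sorted(rng.choice(9, size=k, replace=False))
            pairs = list(zip(map(int, qs), map(int, ts)))
            assert alignment_score(q, t, pairs) <= best + 1e-9

    def test_bad_gap_penalties_rejected(self):
        q = random_profile(5, seed=13)
        with pytest.raises(ConfigError):
            align_profiles(q, q, gap_open=-1.0)


class TestZScores:
    def test_exact_linear_data(self):
        hits = [(2.0 + 3.0 * math.log(lq * lt), lq, lt)
                for lq, lt in [(10, 20), (30, 40), (50, 25), (60, 80),
                               (15, 15), (70, 30), (90, 10), (45, 55),
                               (20, 65), (35, 75)]]
        calib = calibrate_zscores(hits)
        assert calib.slope == pytest.approx(3.0, abs=1e-9)
        assert calib.intercept == pytest.approx(2.0, abs=1e-9)
        assert calib.residual_sd <= 1e-6

    def test_noisy_slope_recovery(self):
        rng = np.random.default_rng(99)
        hits = []
        for _ in range(1000):
            lq, lt = int(rng.integers(10, 200)), int(rng.integers(10, 200))
            s = 1.5 + 2.5 * math.log(lq * lt) + rng.normal(0, 1.0)
            hits.append((s, lq, lt))
        calib = calibrate_zscores(hits)
        x = np.array([math.log(lq * lt) for _, lq, lt in hits])
        se = 1.0 / math.sqrt(np.sum((x - x.mean()) ** 2))
        assert abs(calib.slope - 2.5) < 3 * se

    def test_constant_fallback(self):
        hits = [(5.0, 30, 30)] * 12
        with pytest.warns(UserWarning):
            calib = calibrate_zscores(hits)
        assert calib.slope == 0.0
        assert zscore(5.0, 30, 30, calib) == pytest.approx(0.0)

    def test_zscore_on_and_above_line(self):
        hits = [(2.0 + 3.0 * math.log(lq * lt) + dev, lq, lt)
                for dev, (lq, lt) in zip(
                    [1, -1, 1, -1, 1, -1, 1, -1, 1, -1],
                    [(10, 20), (30, 40), (50, 25), (60, 80), (15, 15),
                     (70, 30), (90, 10), (45, 55), (20, 65), (35, 75)])]
        calib = calibrate_zscores(hits)
        on_line = calib.expected(25, 35)
        assert zscore(on_line, 25, 35, calib) == pytest.approx(0.0, abs=1e-9)
        assert zscore(on_line + calib.residual_sd, 25, 35,
                      calib) == pytest.approx(1.0, abs=1e-9)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(7)
        hits = [(float(rng.normal(10, 2)), int(rng.integers(10, 99)),
                 int(rng.integers(10, 99))) for _ in range(30)]
        calib = calibrate_zscores(hits)
        a, b = 3.0, -4.0
        scaled = [(a * s + b, lq, lt) for s, lq, lt in hits]
        calib2 = calibrate_zscores(scaled)
        for (s, lq, lt) in hits[:5]:
            z1 = zscore(s, lq, lt, calib)
            z2 = zscore(a * s + b, lq, lt, calib2)
            assert z1 == pytest.approx(z2, abs=1e-9)

    def test_true_template_attains_max_zscore(self):
        """In a seeded decoy library, the profile sampled from the same
        ancestral sequence as the query outranks random-sequence decoys."""
        rng = np.random.default_rng(1234)
        letters = np.array(list(AA_ORDER))
        ancestral = "".join(rng.choice(letters, size=60))
        query = build_profile_from_msa(
            fx.sample_msa(ancestral, 20, 0.15, seed=1234), label="query")
        true_template = build_profile_from_msa(
            fx.sample_msa(ancestral, 20, 0.15, seed=4321), label="true")
        library = [true_template]
        for i in range(15):
            decoy_seq = "".join(rng.choice(letters,
                                           size=int(rng.integers(40, 90))))
            library.append(build_profile_from_msa(
                fx.sample_msa(decoy_seq, 20, 0.15, seed=100 + i),
                label=f"decoy{i}"))
        hits = [(align_profiles(query, t).raw_score, query.length, t.length)
                for t in library]
        calib = calibrate_zscores(hits)
        zs = [zscore(s, lq, lt, calib) for s, lq, lt in hits]
        assert int(np.argmax(zs)) == 0


class TestSplitQuery:
    def test_windowing_arithmetic(self):
        prof = random_profile(100, seed=20)
        frags = split_query(prof, 50, overlap=10)
        assert [f.metadata["offset"] for f in frags] == [0, 40, 50]
        covered = set()
        for f in frags:
            covered.update(range(f.metadata["offset"],
                                 f.metadata["offset"] + f.length))
        assert covered == set(range(100))

    def test_short_profile_single_fragment(self):
        prof = random_profile(30, seed=21)
        frags = split_query(prof, 50, overlap=10)
        assert len(frags) == 1
        assert np.array_equal(frags[0].columns, prof.columns)

    def test_exact_cover_no_overlap(self):
        prof = random_profile(40, seed=22)
        frags = split_query(prof, 40, overlap=0)
        assert len(frags) == 1
        assert frags[0].metadata["offset"] == 0
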