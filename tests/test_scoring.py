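import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mu8.aaindex import AAINDEX_RESIDUE_ORDER, standardize_scale
from mu8.alignment import Alignment, crop_to_reference
from mu8.scoring import (
    CScoreMatrix,
    CScoreRow,
    FamilyColumnStats,
    IndexProfile,
    ScoreFilter,
    c_scores,
    conservation_row,
    family_column_stats,
    filter_scores,
    pc1_scale,
    profile_reference,
    score_histogram,
    stack_layout,
)

from conftest import make_scale


def loop_c_scores(ref_seq, family_seqs, scale_values, sigma_floor_frac=0.01):
    """Straight-line reimplementation of the c-score with explicit loops.

    Independent oracle: no numpy vectorization, no shared code with the
    implementation under test.
    """
    L = len(ref_seq)
    means, sds = [], []
    for r in range(L):
        vals = []
        for seq in family_seqs:
            ch = seq[r]
            if ch in scale_values and not math.isnan(scale_values[ch]):
                vals.append(scale_values[ch])
        if vals:
            m = sum(vals) / len(vals)
            means.append(m)
            if len(vals) >= 2:
                sds.append(math.sqrt(sum((v - m) ** 2 for v in vals) / len(vals)))
            else:
                sds.append(math.nan)
        else:
            means.append(math.nan)
            sds.append(math.nan)
    positive = sorted(s for s in sds if not math.isnan(s) and s > 0)
    if positive:
        k = len(positive)
        median = (positive[k // 2] if k % 2 else
                  (positive[k // 2 - 1] + positive[k // 2]) / 2)
        floor = sigma_floor_frac * median
    else:
        floor = 0.0
    out = []
    for r in range(L):
        ch = ref_seq[r]
        if ch not in scale_values or math.isnan(scale_values[ch]) or math.isnan(means[r]):
            out.append(math.nan)
            continue
        sd = sds[r]
        if math.isnan(sd):
            out.append(math.nan)
            continue
        sd_eff = max(sd, floor)
        if sd_eff == 0:
            out.append(math.nan)
            continue
        out.append((scale_values[ch] - means[r]) / sd_eff)
    return out


def make_stats(mean, sd, n=None):
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    n = np.full(len(mean), 5) if n is None else np.asarray(n)
    return FamilyColumnStats(characteristic_id="T", mean=mean, sd=sd, n=n)


def make_row(scores):
    scores = np.asarray(scores, dtype=float)
    return CScoreRow(characteristic_id="T", scores=scores,
                     sigma_floored=np.zeros(len(scores), dtype=bool))


class TestProfileReference:
    def test_lookup(self, ramp_scale):
        prof = profile_reference("AV", ramp_scale)
        assert prof.values[0] == ramp_scale.values["A"]
        assert prof.values[1] == ramp_scale.values["V"]

    def test_x_is_missing(self, ramp_scale):
        prof = profile_reference("AXA", ramp_scale)
        assert not np.isnan(prof.values[0])
        assert np.isnan(prof.values[1])
        assert prof.values[0] == prof.values[2]

    def test_empty_sequence(self, ramp_scale):
        assert profile_reference("", ramp_scale).values.size == 0


class TestFamilyColumnStats:
    def test_identical_residues(self):
        aln = Alignment(records=(("REF", "A"), ("F1", "A"), ("F2", "A")),
                        reference_id="REF")
        scale = make_scale([1.0] + [0.0] * 19)
        st_ = family_column_stats(crop_to_reference(aln), scale)
        assert st_.mean[0] == 1.0 and st_.sd[0] == 0.0 and st_.n[0] == 2

    def test_population_sd_hand_oracle(self):
        # column {A: 1, V: 3}: mean 2, population sd of {1,3} = 1
        aln = Alignment(records=(("REF", "A"), ("F1", "A"), ("F2", "V")),
                        reference_id="REF")
        vals = [0.0] * 20
        vals[0] = 1.0  # A
        vals[19] = 3.0  # V
        st_ = family_column_stats(crop_to_reference(aln), make_scale(vals))
        assert st_.mean[0] == pytest.approx(2.0)
        assert st_.sd[0] == pytest.approx(1.0)

    def test_empty_column(self, ramp_scale):
        aln = Alignment(records=(("REF", "A"), ("F1", "-"), ("F2", "X")),
                        reference_id="REF")
        st_ = family_column_stats(crop_to_reference(aln), ramp_scale)
        assert st_.n[0] == 0
        assert np.isnan(st_.mean[0]) and np.isnan(st_.sd[0])

    def test_single_value_has_mean_no_sd(self, ramp_scale):
        aln = Alignment(records=(("REF", "A"), ("F1", "C"), ("F2", "-")),
                        reference_id="REF")
        st_ = family_column_stats(crop_to_reference(aln), ramp_scale)
        assert st_.n[0] == 1
        assert st_.mean[0] == ramp_scale.values["C"]
        assert np.isnan(st_.sd[0])

    def test_include_reference_flag(self, ramp_scale):
        aln = Alignment(records=(("REF", "A"), ("F1", "C"), ("F2", "C")),
                        reference_id="REF")
        excl = family_column_stats(crop_to_reference(aln), ramp_scale)
        incl = family_column_stats(crop_to_reference(aln), ramp_scale,
                                   include_reference=True)
        assert excl.n[0] == 2 and incl.n[0] == 3
        assert incl.mean[0] != excl.mean[0]


class TestCScores:
    def test_basic_arithmetic(self):
        prof = IndexProfile("T", np.array([5.0]))
        row = c_scores(prof, make_stats([3.0], [1.0]))
        assert row.scores[0] == pytest.approx(2.0)
        assert not row.sigma_floored[0]

    def test_zero_numerator(self):
        prof = IndexProfile("T", np.array([3.0, 3.0]))
        row = c_scores(prof, make_stats([3.0, 3.0], [0.7, 2.5]))
        assert np.all(row.scores == 0.0)

    def test_sigma_floor_policy(self):
        # sigma 0 at r=0; positive sigmas {0.4, 0.5, 0.6} -> median 0.5,
        # floor 0.005, c = (4-3)/0.005 = 200, flagged
        prof = IndexProfile("T", np.array([4.0, 0.0, 0.0, 0.0]))
        row = c_scores(prof, make_stats([3.0, 0.0, 0.0, 0.0],
                                        [0.0, 0.4, 0.5, 0.6]))
        assert row.scores[0] == pytest.approx(200.0)
        assert row.sigma_floored[0]
        assert not row.sigma_floored[1:].any()

    def test_missing_propagates(self):
        prof = IndexProfile("T", np.array([np.nan, 1.0]))
        row = c_scores(prof, make_stats([0.0, np.nan], [1.0, 1.0]))
        assert np.isnan(row.scores).all()

    def test_all_sigma_missing_errors(self):
        prof = IndexProfile("T", np.array([1.0]))
        with pytest.raises(ValueError, match="no family variance"):
            c_scores(prof, make_stats([0.0], [np.nan]))

    def test_length_mismatch(self):
        prof = IndexProfile("T", np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="length mismatch"):
            c_scores(prof, make_stats([0.0], [1.0]))

    def test_oracle_equivalence_toy_alignment(self):
        """5-sequence x 10-column alignment vs explicit-loop oracle."""
        rng = np.random.default_rng(42)
        letters = np.array(list(AAINDEX_RESIDUE_ORDER))
        seqs = ["".join(rng.choice(letters, size=10)) for _ in range(6)]
        aln = Alignment(
            records=tuple((f"S{i}", s) for i, s in enumerate(seqs)),
            reference_id="S0",
        )
        ca = crop_to_reference(aln)
        for k in range(3):
            scale = make_scale(rng.normal(size=20), accession=f"SC{k}")
            prof = profile_reference(ca.reference_seq, scale)
            stats = family_column_stats(ca, scale)
            got = c_scores(prof, stats).scores
            exp = loop_c_scores(ca.reference_seq, [s for _, s in ca.family_records],
                                scale.values)
            np.testing.assert_allclose(got, exp, atol=1e-12)

    def test_reference_equal_to_uniform_family_gives_zero(self):
        # invariant: if the reference residue equals every family residue,
        # the numerator vanishes for every characteristic
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list(AAINDEX_RESIDUE_ORDER), size=8))
        aln = Alignment(
            records=(("REF", seq), ("F1", seq), ("F2", seq), ("F3", seq)),
            reference_id="REF",
        )
        ca = crop_to_reference(aln)
        for k in range(3):
            scale = make_scale(rng.normal(size=20), accession=f"SC{k}")
            row = c_scores(profile_reference(ca.reference_seq, scale),
                           family_column_stats(ca, scale))
            assert np.all(row.scores[np.isfinite(row.scores)] == 0.0)

    @given(st.floats(0.01, 50), st.floats(-20, 20), st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, a, b, seed):
        """v -> a*v + b (a > 0) scales numerator and sigma alike."""
        rng = np.random.default_rng(seed)
        letters = np.array(list(AAINDEX_RESIDUE_ORDER))
        seqs = ["".join(rng.choice(letters, size=12)) for _ in range(5)]
        aln = Alignment(records=tuple((f"S{i}", s) for i, s in enumerate(seqs)),
                        reference_id="S0")
        ca = crop_to_reference(aln)
        v = rng.normal(size=20)
        base = make_scale(v)
        trans = make_scale(a * v + b)
        r1 = c_scores(profile_reference(ca.reference_seq, base),
                      family_column_stats(ca, base)).scores
        r2 = c_scores(profile_reference(ca.reference_seq, trans),
                      family_column_stats(ca, trans)).scores
        np.testing.assert_allclose(r1, r2, atol=1e-9)


def loop_uncentered_pc1(vectors):
    """Brute-force PC1 oracle: assemble the 20x20 second-moment matrix with
    explicit loops and eigendecompose it."""
    n, d = len(vectors), 20
    M = [[0.0] * d for _ in range(d)]
    for i in range(d):
        for j in range(d):
            s = 0.0
            for v in vectors:
                s += v[i] * v[j]
            M[i][j] = s / n
    eigvals, eigvecs = np.linalg.eigh(np.array(M))
    top = np.argmax(eigvals)
    return eigvals[top] / eigvals.sum(), eigvecs[:, top]


class TestPC1:
    def test_identical_copies_rank_one(self):
        base = standardize_scale(make_scale(np.arange(1.0, 21.0)))
        pc = pc1_scale([base, base, base])
        assert pc.variance_explained == pytest.approx(1.0)
        lv = np.array(pc.loadings.as_vector())
        bv = np.array(base.as_vector())
        cos = abs(lv @ bv) / np.linalg.norm(bv)
        assert cos == pytest.approx(1.0, abs=1e-9)

    def test_orthogonal_equal_norm_pair(self):
        v1 = np.zeros(20); v1[0], v1[1] = 1.0, -1.0
        v2 = np.zeros(20); v2[2], v2[3] = 1.0, -1.0
        pc = pc1_scale([make_scale(v1, "A1"), make_scale(v2, "A2")])
        assert pc.variance_explained == pytest.approx(0.5)

    def test_brute_force_eigen_oracle(self):
        rng = np.random.default_rng(11)
        scales = [standardize_scale(make_scale(rng.normal(size=20), f"S{i}"))
                  for i in range(5)]
        pc = pc1_scale(scales)
        exp_var, exp_vec = loop_uncentered_pc1([s.as_vector() for s in scales])
        assert pc.variance_explained == pytest.approx(exp_var, abs=1e-10)
        got = np.array(pc.loadings.as_vector())
        cos = abs(got @ exp_vec)
        assert cos == pytest.approx(1.0, abs=1e-9)
        assert np.linalg.norm(got) == pytest.approx(1.0, abs=1e-9)

    def test_sign_convention_positive_corr_with_mean(self):
        rng = np.random.default_rng(5)
        proto = rng.normal(size=20)
        scales = [standardize_scale(make_scale(proto + 0.1 * rng.normal(size=20), f"S{i}"))
                  for i in range(4)]
        pc = pc1_scale(scales)
        mean_vec = np.mean([s.as_vector() for s in scales], axis=0)
        assert np.array(pc.loadings.as_vector()) @ mean_vec > 0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(6)
        scales = [standardize_scale(make_scale(rng.normal(size=20), f"S{i}"))
                  for i in range(5)]
        a = pc1_scale(scales)
        b = pc1_scale(scales[::-1])
        np.testing.assert_allclose(a.loadings.as_vector(), b.loadings.as_vector(),
                                   atol=1e-10)
        assert a.variance_explained == pytest.approx(b.variance_explained)

    def test_scales_with_missing_dropped(self):
        rng = np.random.default_rng(7)
        good = [standardize_scale(make_scale(rng.normal(size=20), f"G{i}"))
                for i in range(3)]
        vals = rng.normal(size=20); vals[4] = np.nan
        bad = make_scale(vals, "BAD")
        pc = pc1_scale(good + [bad])
        assert pc.n_indices_used == 3

    def test_too_few_scales_errors(self):
        s = standardize_scale(make_scale(np.arange(1.0, 21.0)))
        with pytest.raises(ValueError, match=">=2"):
            pc1_scale([s])


class TestConservationRow:
    def test_min_max(self):
        row = conservation_row(make_stats([0, 0, 0], [0.0, 1.0, 2.0]))
        np.testing.assert_allclose(row.display, [0.0, 0.5, 1.0])

    def test_constant_sigma_all_zero(self):
        row = conservation_row(make_stats([0, 0], [0.7, 0.7]))
        np.testing.assert_allclose(row.display, [0.0, 0.0])

    def test_missing_propagates(self):
        row = conservation_row(make_stats([0, 0, 0], [0.0, np.nan, 2.0]))
        assert np.isnan(row.display[1])
        assert row.display[0] == 0.0 and row.display[2] == 1.0


def loop_histogram(scores, n_bins=40, cap=3.0):
    counts = [0] * n_bins
    lo_c = hi_c = 0
    width = 2 * cap / n_bins
    for s in scores:
        if math.isnan(s):
            continue
        if s < -cap:
            lo_c += 1
            s = -cap
        elif s > cap:
            hi_c += 1
            s = cap
        k = int((s + cap) / width)
        counts[min(k, n_bins - 1)] += 1
    return counts, lo_c, hi_c


class TestScoreHistogram:
    def test_clamping_rule(self):
        h = score_histogram(make_row([-5.0, 0.0, 5.0]))
        assert h.counts[0] == 1 and h.counts[-1] == 1
        assert h.counts[20] == 1  # 0.0 falls in bin [0, 0.15)
        assert h.n_clamped_low == 1 and h.n_clamped_high == 1
        assert h.counts.sum() == 3
        assert len(h.bin_edges) == 41

    def test_empty_row(self):
        h = score_histogram(make_row([]))
        assert h.counts.sum() == 0 and not h.counts.any()

    def test_nan_excluded_from_counts(self):
        h = score_histogram(make_row([np.nan, 1.0]))
        assert h.counts.sum() == 1

    def test_loop_oracle_on_normal_draws(self):
        rng = np.random.default_rng(2024)
        scores = rng.standard_normal(1000)
        h = score_histogram(make_row(scores))
        exp_counts, exp_lo, exp_hi = loop_histogram(list(scores))
        assert h.counts.sum() == 1000
        np.testing.assert_array_equal(h.counts, exp_counts)
        assert (h.n_clamped_low, h.n_clamped_high) == (exp_lo, exp_hi)


class TestFilterScores:
    def test_interval_from_display_filter(self):
        # the -2..-0.5 brushing scenario
        mask = filter_scores(make_row([-1.0, -3.0, 0.2]),
                             ScoreFilter("T", lo=-2.0, hi=-0.5))
        np.testing.assert_array_equal(mask, [True, False, False])

    def test_widest_range_keeps_all_finite(self):
        mask = filter_scores(make_row([-1e9, np.nan, 1e9]),
                             ScoreFilter("T", lo=-np.inf, hi=np.inf))
        np.testing.assert_array_equal(mask, [True, False, True])

    def test_closed_interval_endpoints(self):
        mask = filter_scores(make_row([1.5, 1.4999]), ScoreFilter("T", 1.5, 1.5))
        np.testing.assert_array_equal(mask, [True, False])

    def test_lo_above_hi_rejected(self):
        with pytest.raises(ValueError):
            ScoreFilter("T", lo=1.0, hi=0.0)


class TestStackLayout:
    def _matrix(self, cols):
        """cols: dict characteristic -> list of scores."""
        rows = tuple(
            CScoreRow(characteristic_id=k, scores=np.asarray(v, dtype=float),
                      sigma_floored=np.zeros(len(v), dtype=bool))
            for k, v in cols.items()
        )
        return CScoreMatrix(rows=rows)

    def test_sign_partition(self):
        m = self._matrix({"A": [1.0], "B": [-2.0], "C": [0.0]})
        (ps,) = stack_layout(m)
        assert [(s.characteristic_id, s.magnitude) for s in ps.positive] == [("A", 1.0)]
        assert [(s.characteristic_id, s.magnitude) for s in ps.negative] == [("B", 2.0)]

    def test_all_zero_position(self):
        m = self._matrix({"A": [0.0], "B": [0.0]})
        (ps,) = stack_layout(m)
        assert ps.positive == () and ps.negative == ()

    def test_magnitude_clamped_raw_preserved(self):
        m = self._matrix({"A": [7.0]})
        (ps,) = stack_layout(m)
        (seg,) = ps.positive
        assert seg.magnitude == 3.0
        assert seg.raw_score == 7.0

    def test_segment_order_matches_characteristic_order(self):
        m = self._matrix({"B": [2.0], "A": [1.0]})
        (ps,) = stack_layout(m)
        assert [s.characteristic_id for s in ps.positive] == ["B", "A"]
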