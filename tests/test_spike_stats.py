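"""PSTH binning, small-sample test oracles, FDR, smoothing, windows, ISIs."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from blinklearn import (
    StimulusProtocol,
    TimeWindows,
    bh_fdr,
    bin_spike_counts,
    compute_isis,
    compute_psth,
    first_significant_bin,
    isi_stats,
    per_bin_signed_rank,
    ranksum_windows,
    smooth_pvalues,
    window_spike_counts,
)
from blinklearn.session import SessionStage, UnitRecording

PROTO = StimulusProtocol()


def make_unit(trains, unit_id="u0"):
    return UnitRecording(
        unit_id=unit_id,
        stage=SessionStage.initial,
        trains=[np.asarray(t, dtype=float) for t in trains],
        trial_kinds=[],
    )


# -- independent oracles ------------------------------------------------------


def signed_rank_enumeration_p(x):
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns."""
    x = np.asarray(x, dtype=float)
    ranks = np.argsort(np.argsort(np.abs(x))) + 1.0
    w_obs = ranks[x > 0].sum()
    w_all = np.array(
        [ranks[np.array(signs)].sum() for signs in itertools.product([False, True], repeat=x.size)]
    )
    p_le = np.mean(w_all <= w_obs)
    p_ge = np.mean(w_all >= w_obs)
    return min(1.0, 2 * min(p_le, p_ge))


def ranksum_enumeration_p(a, b):
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    pooled = np.concatenate([a, b])
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    n_a = len(a)
    w_obs = ranks[:n_a].sum()
    w_all = np.array(
        [ranks[list(idx)].sum() for idx in itertools.combinations(range(len(pooled)), n_a)]
    )
    p_le = np.mean(w_all <= w_obs)
    p_ge = np.mean(w_all >= w_obs)
    return min(1.0, 2 * min(p_le, p_ge))


def bh_stepup_bruteforce(p, q):
    """Literal step-up scan of the BH definition."""
    m = len(p)
    order = np.argsort(p)
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


# -- binning ------------------------------------------------------------------


class TestBinning:
    def test_spikes_land_in_half_open_bins(self):
        unit = make_unit([[0.005, 0.012]])
        edges, mat = bin_spike_counts([unit], PROTO)
        left = edges[:-1]
        b1 = np.flatnonzero(np.isclose(left, 0.0))[0]
        b2 = np.flatnonzero(np.isclose(left, 0.010))[0]
        assert mat[0, b1] == 1 and mat[0, b2] == 1
        assert mat.sum() == 2

    def test_default_grid_has_300_bins(self):
        edges, mat = bin_spike_counts([make_unit([[]])], PROTO)
        assert mat.shape == (1, 300)
        assert edges[0] == -1.0 and edges[-1] == pytest.approx(2.0)

    def test_empty_trains_give_zero_matrix(self):
        _, mat = bin_spike_counts([make_unit([[], []])], PROTO)
        assert not mat.any()

    def test_count_conservation_on_random_trains(self):
        rng = np.random.default_rng(0)
        units = []
        totals = []
        for u in range(5):
            trains = [np.sort(rng.uniform(-1, 2, size=rng.integers(0, 50))) for _ in range(4)]
            units.append(make_unit(trains, f"u{u}"))
            totals.append(sum(t.size for t in trains))
        _, mat = bin_spike_counts(units, PROTO)
        np.testing.assert_allclose(mat.sum(axis=1) * 4, totals)

    def test_nonpositive_bin_rejected(self):
        with pytest.raises(ValueError):
            bin_spike_counts([make_unit([[]])], PROTO, bin_s=0.0)


# -- signed rank --------------------------------------------------------------


class TestSignedRank:
    def test_six_positive_values_exact_p(self):
        # all ranks positive: two-sided p = 2 * (1/2^6) = 0.03125
        mat = np.column_stack([np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])])
        assert per_bin_signed_rank(mat)[0] == pytest.approx(0.03125)

    def test_all_zero_column_is_p_one(self):
        mat = np.zeros((4, 2))
        np.testing.assert_array_equal(per_bin_signed_rank(mat), [1.0, 1.0])

    def test_single_unit_rejected(self):
        with pytest.raises(ValueError):
            per_bin_signed_rank(np.ones((1, 3)))

    def test_matches_sign_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        for n in range(3, 11):
            for _ in range(5):
                col = rng.normal(size=n)
                p_impl = per_bin_signed_rank(col[:, None])[0]
                assert p_impl == pytest.approx(signed_rank_enumeration_p(col), abs=1e-12)


# -- BH FDR -------------------------------------------------------------------


class TestBhFdr:
    def test_hand_stepup_example_rejects_all_four(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        p_adj, mask = bh_fdr(p, q=0.05)
        assert mask.all()
        np.testing.assert_allclose(p_adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_pvalue_reduces_to_threshold(self):
        assert bh_fdr(np.array([0.04]), q=0.05)[1][0]
        assert not bh_fdr(np.array([0.06]), q=0.05)[1][0]

    def test_matches_stepup_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            m = rng.integers(1, 40)
            p = rng.uniform(size=m)
            for q in (0.01, 0.05, 0.2):
                _, mask = bh_fdr(p, q)
                np.testing.assert_array_equal(mask, bh_stepup_bruteforce(p, q))

    def test_adjusted_p_monotone_in_rank(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=30)
        p_adj, _ = bh_fdr(p, 0.05)
        order = np.argsort(p)
        assert np.all(np.diff(p_adj[order]) >= -1e-15)

    def test_rejections_never_decrease_with_q(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=50) ** 2
        masks = [bh_fdr(p, q)[1] for q in (0.01, 0.05, 0.1, 0.2)]
        for lo, hi in zip(masks, masks[1:]):
            assert np.all(hi | ~lo)

    def test_bad_q_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5]), q=1.5)


# -- smoothing and onset ------------------------------------------------------


class TestSmoothing:
    def test_constant_vector_unchanged(self):
        np.testing.assert_allclose(smooth_pvalues(np.full(10, 0.3)), 0.3)

    def test_tiny_span_is_identity(self):
        p = np.array([0.1, 0.9, 0.2])
        np.testing.assert_array_equal(smooth_pvalues(p, span=0.3), p)  # window 1

    def test_window_three_with_truncated_edges(self):
        out = smooth_pvalues(np.array([0.0, 1.0, 0.0]), span=1.0)
        np.testing.assert_allclose(out, [0.5, 1 / 3, 0.5])

    def test_bad_span_rejected(self):
        with pytest.raises(ValueError):
            smooth_pvalues(np.array([0.5]), span=0.0)


class TestFirstSignificantBin:
    EDGES = np.arange(-1.0, 2.0 + 1e-9, 0.010)

    def test_no_significant_bins_gives_none(self):
        assert first_significant_bin(np.zeros(300, bool), self.EDGES) is None

    def test_reads_left_edge_of_first_post_cs_bin(self):
        mask = np.zeros(300, bool)
        mask[np.flatnonzero(np.isclose(self.EDGES[:-1], 0.060))[0]] = True
        assert first_significant_bin(mask, self.EDGES) == pytest.approx(0.060)

    def test_pre_cs_bins_ignored(self):
        mask = np.zeros(300, bool)
        mask[10] = True  # -0.9 s
        assert first_significant_bin(mask, self.EDGES) is None
        assert first_significant_bin(mask, self.EDGES, from_s=-1.0) == pytest.approx(-0.9)


# -- windows ------------------------------------------------------------------


class TestWindows:
    def test_one_spike_per_window(self):
        unit = make_unit([[-0.5, 0.1, 0.3, 1.0]], "u0")
        out = window_spike_counts([unit, make_unit([[]], "u1")], PROTO)
        for name in ("spontaneous", "cs", "cs_us", "late"):
            assert out[name].sum() == 1.0

    def test_window_bin_counts_have_expected_sizes(self):
        out = window_spike_counts([make_unit([[]])], PROTO)
        assert out["spontaneous"].size == 100
        assert out["cs"].size == 25
        assert out["cs_us"].size == 10
        assert out["late"].size == 165

    def test_windows_are_disjoint_and_inside_epoch(self):
        w = TimeWindows()
        intervals = [v for _, v in w.items()]
        for (a0, a1), (b0, b1) in zip(intervals, intervals[1:]):
            assert a1 <= b0
        assert intervals[0][0] >= PROTO.epoch_start_s
        assert intervals[-1][1] <= PROTO.epoch_end_s

    def test_homogeneous_rate_fills_all_windows_evenly(self):
        rng = np.random.default_rng(5)
        trains = [np.sort(rng.uniform(-1, 2, rng.poisson(30))) for _ in range(200)]
        out = window_spike_counts([make_unit(trains)], PROTO)
        for name, vals in out.items():
            assert vals.mean() == pytest.approx(0.1, abs=0.02)


class TestRanksum:
    def test_symmetric_tiny_samples_give_p_one(self):
        assert ranksum_windows([1.0, 4.0], [2.0, 3.0]) == pytest.approx(1.0)

    def test_extreme_separation_exact_p(self):
        # most extreme of C(6,3)=20 orderings: two-sided p = 2/20
        assert ranksum_windows([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            a = rng.normal(size=rng.integers(2, 8))
            b = rng.normal(size=rng.integers(2, 8))
            assert ranksum_windows(a, b) == pytest.approx(
                ranksum_enumeration_p(a, b), abs=1e-12
            )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ranksum_windows([], [1.0])

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(7)
        n_rep, alpha = 2000, 0.05
        rejects = sum(
            ranksum_windows(rng.normal(size=30), rng.normal(size=30)) < alpha
            for _ in range(n_rep)
        )
        se = np.sqrt(alpha * (1 - alpha) / n_rep)
        assert rejects / n_rep == pytest.approx(alpha, abs=3 * se)


# -- ISIs ---------------------------------------------------------------------


class TestIsis:
    def test_consecutive_in_window_pairs(self):
        isis = compute_isis(np.array([0.010, 0.014, 0.020]), (0.0, 0.25))
        np.testing.assert_allclose(isis, [4.0, 6.0])

    def test_single_in_window_spike_has_no_isi(self):
        assert compute_isis(np.array([-0.5, 0.1, 0.5]), (0.0, 0.25)).size == 0

    def test_matches_bruteforce_pair_filter(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            train = np.sort(rng.uniform(-1, 2, size=40))
            window = (0.0, 0.35)
            expected = [
                1000.0 * (b - a)
                for a, b in zip(train, train[1:])
                if window[0] <= a < window[1] and window[0] <= b < window[1]
            ]
            np.testing.assert_allclose(compute_isis(train, window), expected)

    def test_hand_histogram_and_stats(self):
        s = isi_stats(np.array([3.0, 3.5, 9.0]))
        np.testing.assert_array_equal(s.histogram, [2, 0, 1])
        assert s.mode_ms == 2.0  # center of the [0, 4) bin
        assert s.median_ms == 3.5
        assert s.mean_ms == pytest.approx(31 / 6)

    def test_single_isi(self):
        s = isi_stats(np.array([7.0]))
        assert s.median_ms == s.mean_ms == 7.0
        assert s.mode_ms == 6.0  # center of [4, 8)

    def test_exponential_sample_mean_within_3_se(self):
        rng = np.random.default_rng(9)
        lam = 0.05  # per ms -> mean 20 ms
        sample = rng.exponential(1 / lam, size=100_000)
        s = isi_stats(sample)
        se = (1 / lam) / np.sqrt(sample.size)
        assert s.mean_ms == pytest.approx(1 / lam, abs=3 * se)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            isi_stats(np.array([]))


# -- full PSTH pipeline -------------------------------------------------------


class TestComputePsth:
    def test_counts_and_masks_are_consistent(self):
        rng = np.random.default_rng(10)
        units = [
            make_unit([np.sort(rng.uniform(-1, 2, 30)) for _ in range(10)], f"u{u}")
            for u in range(6)
        ]
        res = compute_psth(units, PROTO)
        assert res.per_unit_counts.shape == (6, 300)
        assert res.p_raw.shape == res.p_adjusted.shape == res.sig_mask.shape == (300,)
        assert np.all((res.p_raw >= 0) & (res.p_raw <= 1))
        assert np.all(res.p_adjusted >= res.p_raw - 1e-15)
        np.testing.assert_allclose(res.mean_counts, res.per_unit_counts.mean(axis=0))

    def test_stimulus_locked_burst_detected_at_its_onset(self):
        # >= 20 units: the exact signed-rank p floor 2/2^n must be able to
        # clear the BH threshold q/m over 300 bins
        rng = np.random.default_rng(11)
        units = []
        for u in range(20):
            trains = []
            for _ in range(20):
                base = rng.uniform(-1, 2, rng.poisson(15))
                burst = rng.uniform(0.25, 0.35, rng.poisson(8))
                trains.append(np.sort(np.concatenate([base, burst])))
            units.append(make_unit(trains, f"u{u}"))
        res = compute_psth(units, PROTO, q=0.01)
        assert res.onset_latency_s == pytest.approx(0.25, abs=0.02)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=60), st.sampled_from([0.01, 0.05, 0.1]))
def test_bh_property_matches_definition(p, q):
    """BH rejections equal the literal step-up scan for arbitrary p-vectors."""
    p = np.asarray(p)
    _, mask = bh_fdr(p, q)
    np.testing.assert_array_equal(mask, bh_stepup_bruteforce(p, q))
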