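"""Rhythm detection: time-of-day folds, dusk/dawn t-test against the textbook
formula, umbrella rank test against exhaustive permutation oracles, and the
Benjamini–Hochberg step-up."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dielflux.rhythm import (
    _enumerate_assignments,
    _mack_wolfe_moments,
    _umbrella_candidates,
    benjamini_hochberg,
    diel_statistics,
    dusk_dawn_test,
    rain_test,
    time_of_day_average,
)
from dielflux.simulate import generate_diel_series


def _frame(hours, values, reps=1):
    ts = pd.Timestamp("2015-07-26") + pd.to_timedelta(np.repeat(hours, reps), unit="h")
    return pd.DataFrame(
        {"datetime_local": ts, "concentration": np.repeat(values, reps)}
    )


# ---------------------------------------------------------------------------
# time-of-day averaging
# ---------------------------------------------------------------------------

class TestTimeOfDayAverage:
    def test_constant_series_all_folds_one(self):
        hours = np.arange(0, 96, 4.0) + 6
        st = time_of_day_average(_frame(hours, np.full(hours.size, 3.7)))
        assert all(v == pytest.approx(1.0) for v in st.tod_fold.values())

    def test_two_day_fold_arithmetic(self):
        # 06:00 values (1, 1); 18:00 values (2, 3) -> fold(18) = 2.5
        hours = np.array([6.0, 18.0, 30.0, 42.0])
        st = time_of_day_average(_frame(hours, np.array([1.0, 2.0, 1.0, 3.0])))
        assert st.tod_fold[18.0] == pytest.approx(2.5)
        assert st.tod_fold[6.0] == 1.0

    def test_replicates_averaged_before_days(self):
        # day 1 has 3 replicates at 18:00, day 2 has 1: per-timepoint averaging
        # first means fold(18) = mean(2, 4) / 1 = 3, not mean(2,2,2,4)
        df = pd.concat(
            [
                _frame(np.array([6.0]), np.array([1.0])),
                _frame(np.array([18.0]), np.array([2.0]), reps=3),
                _frame(np.array([30.0]), np.array([1.0])),
                _frame(np.array([42.0]), np.array([4.0])),
            ]
        )
        st = time_of_day_average(df)
        assert st.tod_fold[18.0] == pytest.approx(3.0)

    def test_missing_reference_hour_reported(self):
        hours = np.array([0.0, 12.0, 24.0, 36.0])
        with pytest.raises(ValueError, match="available hours"):
            time_of_day_average(_frame(hours, np.ones(4)), ref_hour=6.0)

    def test_noiseless_generator_fold_amplitude_exact(self, noiseless_tag_config):
        df = generate_diel_series(noiseless_tag_config)
        st = time_of_day_average(df)
        assert st.fold_amplitude == pytest.approx(2.3, abs=1e-12)

    def test_scale_invariance(self, noisy_tag_config):
        df = generate_diel_series(noisy_tag_config)
        st1 = time_of_day_average(df)
        df2 = df.assign(concentration=df["concentration"] * 17.3)
        st2 = time_of_day_average(df2)
        assert st1.fold_amplitude == pytest.approx(st2.fold_amplitude)


# ---------------------------------------------------------------------------
# dusk vs dawn t-test
# ---------------------------------------------------------------------------

class TestDuskDawnTest:
    @staticmethod
    def _make(dawn_vals, dusk_vals):
        n = len(dawn_vals)
        hours = np.concatenate([6 + 24.0 * np.arange(n), 18 + 24.0 * np.arange(len(dusk_vals))])
        return _frame(hours, np.concatenate([dawn_vals, dusk_vals]))

    def test_identical_groups(self):
        df = self._make([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        t, dof, p = dusk_dawn_test(df)
        assert (t, p) == (0.0, 1.0)
        assert dof == 4

    def test_zero_variance_distinct_groups(self):
        df = self._make([1.0] * 5, [2.0] * 5)
        t, dof, p = dusk_dawn_test(df)
        assert t == -math.inf and p == 0.0

    def test_matches_textbook_pooled_t(self):
        dawn = np.array([1.0, 1.2, 0.9, 1.1, 1.0])
        dusk = np.array([2.1, 2.6, 1.9, 2.4, 2.2])
        t, dof, p = dusk_dawn_test(self._make(dawn, dusk))
        # independent hand computation of the pooled two-sample t
        sp2 = (dawn.var(ddof=1) * 4 + dusk.var(ddof=1) * 4) / 8
        t_hand = (dawn.mean() - dusk.mean()) / math.sqrt(sp2 * (1 / 5 + 1 / 5))
        p_hand = 2 * sps.t.sf(abs(t_hand), 8)
        assert dof == 8
        assert t == pytest.approx(t_hand, rel=1e-12)
        assert p == pytest.approx(p_hand, rel=1e-12)

    def test_single_day_group_rejected(self):
        df = self._make([1.0], [2.0, 2.1])
        with pytest.raises(ValueError, match="daily values"):
            dusk_dawn_test(df)


# ---------------------------------------------------------------------------
# umbrella rank test
# ---------------------------------------------------------------------------

def _oracle_exact_rain(values, group_indices, candidates):
    """Brute-force all-permutation min-p oracle, written independently.

    Enumerates every distinct split of the pooled values into the
    time-ordered groups with plain itertools, scores each candidate umbrella
    with nested loops, converts statistics to per-candidate survival
    p-values, and returns P(min-p <= observed min-p).
    """
    vals = np.asarray(values, float)
    n = len(vals)

    def u_count(a, b):
        s = 0.0
        for x in a:
            for y in b:
                s += (x < y) + 0.5 * (x == y)
        return s

    def stat(groups, rise_idx, fall_idx):
        a = 0.0
        for i in range(len(rise_idx)):
            for j in range(i + 1, len(rise_idx)):
                a += u_count(groups[rise_idx[i]], groups[rise_idx[j]])
        for i in range(len(fall_idx)):
            for j in range(i + 1, len(fall_idx)):
                a += u_count(groups[fall_idx[j]], groups[fall_idx[i]])
        return a

    sizes = [len(g) for g in group_indices]

    # enumerate all distinct assignments
    assignments = []
    idx = list(range(n))
    for g0 in itertools.combinations(idx, sizes[0]):
        rest0 = [i for i in idx if i not in g0]
        for g1 in itertools.combinations(rest0, sizes[1]):
            g2 = tuple(i for i in rest0 if i not in g1)
            assignments.append((g0, g1, g2))

    all_stats = np.empty((len(assignments), len(candidates)))
    for a_i, groups_idx in enumerate(assignments):
        groups = [vals[list(g)] for g in groups_idx]
        for c_i, (_, _, rise_idx, fall_idx) in enumerate(candidates):
            all_stats[a_i, c_i] = stat(groups, rise_idx, fall_idx)

    groups_obs = [vals[list(g)] for g in group_indices]
    obs_stats = np.array(
        [stat(groups_obs, ri, fi) for _, _, ri, fi in candidates]
    )

    total = len(assignments)
    pmat = np.empty_like(all_stats)
    p_obs = np.empty(len(candidates))
    for c_i in range(len(candidates)):
        col = all_stats[:, c_i]
        pmat[:, c_i] = [(col >= s - 1e-9).sum() / total for s in col]
        p_obs[c_i] = (col >= obs_stats[c_i] - 1e-9).sum() / total
    minp = pmat.min(axis=1)
    return (minp <= p_obs.min() + 1e-12).sum() / total


class TestRainTest:
    def test_constant_input_p_one(self):
        hours = np.arange(0, 72, 4.0)
        res = rain_test((hours, np.full(hours.size, 2.0)))
        assert res.p_value == 1.0

    def test_less_than_two_cycles_rejected(self):
        hours = np.arange(0, 24, 4.0)
        with pytest.raises(ValueError, match="cycles"):
            rain_test((hours, np.sin(hours)))

    def test_two_group_single_rise_is_exact_mann_whitney(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=6) + 0.8
        hours = np.concatenate([24.0 * np.arange(6), 12 + 24.0 * np.arange(6)])
        res = rain_test((hours, np.concatenate([x, y])), phases=[1], rise_lengths=[1])
        mw = sps.mannwhitneyu(y, x, alternative="greater", method="exact")
        assert res.p_value == pytest.approx(mw.pvalue, rel=1e-12)

    def test_matches_all_permutation_oracle_3x4(self):
        # noiseless saw-tooth peaking mid-cycle: 3 timepoints x 4 cycles
        cycle = np.array([1.0, 3.0, 2.0])
        values = np.tile(cycle, 4)
        hours = np.concatenate([8.0 * np.arange(3) + 24 * k for k in range(4)])
        res = rain_test((hours, values))
        candidates = _umbrella_candidates(3, None, None)
        groups = [tuple(np.flatnonzero(np.mod(hours, 24) == ph)) for ph in (0, 8, 16)]
        p_oracle = _oracle_exact_rain(values, groups, candidates)
        assert res.method.startswith("exact")
        assert res.p_value == pytest.approx(p_oracle, rel=1e-12)

    def test_matches_oracle_with_noise_and_ties(self, rng):
        # continuous values with injected ties exercise the 0.5-tie handling
        values = np.round(rng.normal(size=12), 1)
        hours = np.concatenate([8.0 * np.arange(3) + 24 * k for k in range(4)])
        res = rain_test((hours, values))
        if res.method == "degenerate":
            return
        candidates = _umbrella_candidates(3, None, None)
        groups = [tuple(np.flatnonzero(np.mod(hours, 24) == ph)) for ph in (0, 8, 16)]
        p_oracle = _oracle_exact_rain(values, groups, candidates)
        assert res.p_value == pytest.approx(p_oracle, rel=1e-12)

    @pytest.mark.parametrize("peak,rise", [(1, 1), (2, 2), (0, 3)])
    def test_moments_match_enumeration_distribution(self, rng, peak, rise):
        # closed-form Mack-Wolfe mean/variance vs the exact null, untied data
        from dielflux.rhythm import _pairwise_u, _umbrella_statistic

        sizes = [3, 2, 3, 2]
        values = rng.normal(size=10)
        labels = _enumerate_assignments(sizes)
        assert labels.shape[0] == math.factorial(10) // (6 * 2 * 6 * 2)
        cand = {
            (p, r): (ri, fi) for p, r, ri, fi in _umbrella_candidates(4, None, None)
        }
        rise_idx, fall_idx = cand[(peak, rise)]
        stats_full = []
        for row in labels:
            groups = [values[row == g] for g in range(4)]
            u = _pairwise_u(groups)
            stats_full.append(_umbrella_statistic(u, rise_idx, fall_idx))
        mean, var = _mack_wolfe_moments(np.array(sizes, float), rise_idx, fall_idx)
        assert np.mean(stats_full) == pytest.approx(mean, rel=1e-12)
        assert np.var(stats_full) == pytest.approx(var, rel=1e-9)

    def test_monotone_transform_invariance(self, noisy_tag_config):
        df = generate_diel_series(noisy_tag_config)
        p1 = rain_test(df).p_value
        df2 = df.assign(concentration=np.log(df["concentration"]))
        p2 = rain_test(df2).p_value
        df3 = df.assign(concentration=df["concentration"] * 3.0 + 1.0)
        p3 = rain_test(df3).p_value
        assert p1 == p2 == p3

    def test_detects_generator_rhythm_with_dusk_peak(self, noisy_tag_config):
        df = generate_diel_series(noisy_tag_config)
        res = rain_test(df)
        assert res.p_value < 0.01
        # best candidate peaks at the configured dusk peak (clock 18:00)
        assert res.peak_phase_h == pytest.approx(18.0)

    def test_bonferroni_option_is_more_conservative(self, noisy_tag_config):
        df = generate_diel_series(noisy_tag_config.with_(noise_cv=0.5, seed=11))
        p_perm = rain_test(df).p_value
        p_bonf = rain_test(df, correction="bonferroni").p_value
        assert p_bonf >= p_perm or p_bonf == pytest.approx(p_perm, abs=0.05)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.01]) == pytest.approx([0.01])

    def test_hand_step_up_example(self):
        # p_(i) * n / i stepped up: (.04, .04, .04, .04)
        out = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert out == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert benjamini_hochberg([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2])

    def test_monotone_and_order_preserving(self, rng):
        p = rng.uniform(size=20)
        adj = benjamini_hochberg(p)
        assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)
        # order preservation is weak: smaller p never gets a larger adjustment
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


# ---------------------------------------------------------------------------
# per-class driver
# ---------------------------------------------------------------------------

class TestDielStatistics:
    def test_adjusted_p_at_least_raw(self, noisy_tag_config):
        cfg = noisy_tag_config  # default has one class; add defaults for variety
        from dielflux.simulate import DEFAULT_CLASSES

        df = generate_diel_series(cfg.with_(classes=DEFAULT_CLASSES))
        stats = diel_statistics(df)
        assert len(stats) == 3
        for s in stats:
            assert s.rain_p_adj >= s.rain_p - 1e-15
            assert s.tod_fold[6.0] == pytest.approx(1.0)
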