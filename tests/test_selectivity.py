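"""Single-unit statistics: rates, differential index, permutation tests,
category recovery, KLD stability and CR correlation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lecpipe._rng import stage_rng
from lecpipe.selectivity import (
    bin_size_sweep,
    classify_unit,
    cr_correlation,
    cs_responsive_test,
    differential_index,
    kld,
    selectivity_table,
    shuffle_corrected_di,
    stability_klds,
    window_rate,
    window_rates,
)
from lecpipe.synth import CellParams, make_schedule, simulate_spikes
from lecpipe.types import AnalysisConfig, SpikeTrainSet, Unit, ValidationError

from conftest import six_block_schedule


class TestWindowRate:
    def test_three_spikes_in_600ms_is_5hz(self):
        assert window_rate(np.array([0.1, 0.2, 0.5]), 0.0, 0.6) == pytest.approx(5.0)

    def test_empty_train_is_zero(self):
        assert window_rate(np.array([]), 0.0, 1.0) == 0.0

    def test_half_open_window_excludes_end(self):
        assert window_rate(np.array([0.6]), 0.0, 0.6) == 0.0
        assert window_rate(np.array([0.0]), 0.0, 0.6) == pytest.approx(1 / 0.6)

    def test_zero_length_window_errors(self):
        with pytest.raises(ValidationError):
            window_rate(np.array([1.0]), 0.5, 0.5)


class TestDifferentialIndex:
    @pytest.mark.parametrize("fr1,fr2,expected", [
        (3.0, 1.0, 0.5), (5.0, 0.0, 1.0), (2.0, 2.0, 0.0), (0.0, 4.0, 1.0),
    ])
    def test_known_values(self, fr1, fr2, expected):
        assert differential_index(fr1, fr2) == pytest.approx(expected)

    def test_both_zero_is_undefined(self):
        assert np.isnan(differential_index(0.0, 0.0))

    @settings(derandomize=True, max_examples=100)
    @given(a=st.floats(0.01, 100), b=st.floats(0.01, 100), k=st.floats(0.01, 50))
    def test_symmetry_and_scale_invariance(self, a, b, k):
        assert differential_index(a, b) == pytest.approx(differential_index(b, a))
        assert differential_index(k * a, k * b) == pytest.approx(differential_index(a, b))
        assert 0.0 <= differential_index(a, b) <= 1.0


class TestResponsivenessTest:
    def test_identical_rates_never_significant(self):
        r = np.array([1.0, 2.0, 0.5, 3.0, 1.5])
        res = cs_responsive_test(r, r.copy(), n_perm=200, rng=np.random.default_rng(0))
        assert res.statistic == 0.0 and not res.significant

    def test_strong_rate_change_detected(self):
        rng = np.random.default_rng(1)
        power = np.mean([
            cs_responsive_test(rng.poisson(6.0, 50) / 0.6, rng.poisson(1.0, 50),
                               n_perm=500, rng=rng).significant
            for _ in range(50)])
        assert power > 0.99

    def test_permutation_matches_exhaustive_enumeration(self):
        """Sampled null quantile lands on the enumerated-null quantile."""
        rng = np.random.default_rng(42)
        hits = 0
        for i in range(20):
            tr = rng.poisson(1.0, 10).astype(float)
            pre = rng.poisson(1.0, 10).astype(float)
            ex = cs_responsive_test(tr, pre, exact=True)
            pm = cs_responsive_test(tr, pre, n_perm=20000, rng=np.random.default_rng(i))
            hits += ex.threshold == pm.threshold
        assert hits >= 18

    def test_low_permutation_count_warns(self):
        with pytest.warns(UserWarning):
            cs_responsive_test(np.array([1.0, 2.0]), np.array([0.5, 1.0]),
                               n_perm=10, alpha=0.05, rng=np.random.default_rng(0))


class TestShuffleCorrectedDi:
    def test_identical_conditions_not_selective(self):
        r = np.array([1.0, 2.0, 0.5, 3.0, 1.5, 2.5])
        res = shuffle_corrected_di(r, r.copy(), 200, rng=np.random.default_rng(0))
        assert res.di_corrected <= 0 and not res.selective

    def test_corrected_never_exceeds_raw(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            res = shuffle_corrected_di(rng.poisson(2.0, 20).astype(float),
                                       rng.poisson(2.0, 50).astype(float),
                                       300, rng=rng)
            if np.isfinite(res.di_raw):
                assert res.di_corrected <= res.di_raw

    def test_large_effect_detected_with_high_power(self):
        rng = np.random.default_rng(4)
        power = np.mean([
            shuffle_corrected_di(rng.poisson(6.0, 20) / 0.6, rng.poisson(0.6, 50) / 0.6,
                                 500, rng=rng).selective
            for _ in range(50)])
        assert power > 0.99

    def test_all_zero_rates_flagged_undefined(self):
        res = shuffle_corrected_di(np.zeros(5), np.zeros(8), 100,
                                   rng=np.random.default_rng(0))
        assert np.isnan(res.di_raw) and not res.selective

    def test_permutation_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(7)
        hits = 0
        for i in range(20):
            a = rng.poisson(1.5, 8).astype(float)
            b = rng.poisson(1.5, 9).astype(float)
            if a.sum() + b.sum() == 0:
                continue
            ex = shuffle_corrected_di(a, b, exact=True)
            pm = shuffle_corrected_di(a, b, 20000, rng=np.random.default_rng(i))
            hits += ex.threshold == pm.threshold
        assert hits >= 18

    def test_null_type_i_error_near_alpha(self):
        """Empirical selective fraction on null cells ~ alpha (quick check;
        the full-scale calibration lives in the acceptance suite)."""
        rng = np.random.default_rng(8)
        n_sel = sum(
            shuffle_corrected_di(rng.poisson(1.2, 20) / 0.6, rng.poisson(1.2, 50) / 0.6,
                                 500, rng=rng).selective
            for _ in range(200))
        frac = n_sel / 200
        ci = 2.58 * np.sqrt(0.05 * 0.95 / 200)
        assert abs(frac - 0.05) < ci + 0.01


class TestCategoryRecovery:
    def test_ground_truth_categories_recovered(self, small_session, fast_cfg):
        spikes, trials, schedule, truth = small_session
        table = selectivity_table(spikes, trials, schedule, fast_cfg, seed=1)
        truth_cat = {c.unit_id: c.category_label for c in truth["cells"]}
        got = table.set_index("unit_id")["category_iti"]
        acc = np.mean([got[u] == truth_cat[u] for u in got.index])
        assert acc >= 0.8  # tighter bound checked at full scale in acceptance

    def test_responsiveness_recovered(self, small_session, fast_cfg):
        """Phasic cells are all detected; the any-of-six-blocks rule inflates
        the family-wise false-positive rate on non-phasic cells to roughly
        1 - 0.95**6 ~ 0.26, which is deliberate (no correction is applied)."""
        spikes, trials, schedule, truth = small_session
        table = selectivity_table(spikes, trials, schedule, fast_cfg, seed=1)
        truth_resp = {c.unit_id: c.responsive for c in truth["cells"]}
        got = table.set_index("unit_id")["responsive"]
        resp = [u for u in got.index if truth_resp[u]]
        nonresp = [u for u in got.index if not truth_resp[u]]
        assert np.mean([got[u] for u in resp]) >= 0.9
        assert np.mean([got[u] for u in nonresp]) <= 0.5


class TestKld:
    def test_uniform_vs_uniform_is_zero(self):
        u = np.full(15, 1 / 15)
        assert kld(u, u) == pytest.approx(0.0)

    def test_point_mass_vs_uniform_is_log2_n(self):
        p = np.zeros(15)
        p[3] = 1.0
        assert kld(p, np.full(15, 1 / 15)) == pytest.approx(np.log2(15))

    def test_two_point_mass_closed_form(self):
        p = np.zeros(15)
        p[0] = p[1] = 0.5
        assert kld(p, np.full(15, 1 / 15)) == pytest.approx(np.log2(7.5))

    def test_zero_q_entry_errors(self):
        q = np.full(15, 1 / 14)
        q[0] = 0.0
        with pytest.raises(ValidationError):
            kld(np.full(15, 1 / 15), q)

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0.01, 10), min_size=3, max_size=12))
    def test_non_negative_and_zero_iff_equal(self, raw):
        p = np.array(raw) / np.sum(raw)
        q = np.full(len(p), 1 / len(p))
        assert kld(p, q) >= -1e-12
        assert kld(p, p.clip(1e-12)) == pytest.approx(0.0, abs=1e-9)


class TestStability:
    def test_metronome_cell_has_zero_klds(self):
        """A perfectly regular spike train yields flat profiles: both KLDs 0."""
        sched = six_block_schedule(3, 3)
        trials = make_schedule(sched, stage_rng(0, "s"))
        end = trials.end_s + 1
        unit = Unit("u0", np.arange(0.0, end, 0.01))  # 100 Hz metronome
        res = stability_klds(unit, trials, sched, AnalysisConfig())
        assert res.within_kld == pytest.approx(0.0, abs=1e-9)
        assert res.between_kld == pytest.approx(0.0, abs=1e-9)

    def test_tonic_block_code_gives_between_above_within(self, blocked_session):
        spikes, trials, schedule, _ = blocked_session
        cfg = AnalysisConfig()
        diffs = [stability_klds(u, trials, schedule, cfg).kld_difference for u in spikes]
        assert np.mean(np.array(diffs) > 0) >= 0.9


class TestBinSweep:
    def test_partition_one_matches_full_window_classification(self, small_session, fast_cfg):
        spikes, trials, schedule, _ = small_session
        sub = SpikeTrainSet(list(spikes)[:6])
        sweep = bin_size_sweep(sub, trials, schedule, fast_cfg, partitions=(1,), seed=3)
        table = selectivity_table(sub, trials, schedule, fast_cfg, seed=3)
        full = table.set_index("unit_id")["category_iti"]
        for row in sweep.itertuples():
            assert row.selective == (row.category != "Non-S")
        # same rates, same machinery: verdicts agree up to permutation noise
        agree = [full[r.unit_id] == r.category for r in sweep.itertuples()]
        assert np.mean(agree) >= 0.8

    def test_selective_fraction_shrinks_with_bin_size(self, small_session):
        """Shorter bins estimate rates more noisily, so fewer cells pass."""
        spikes, trials, schedule, _ = small_session
        cfg = AnalysisConfig(n_permutations=200, rng_seed=5)
        sweep = bin_size_sweep(spikes, trials, schedule, cfg, partitions=(1, 8), seed=5)
        frac = sweep.groupby("partition")["selective"].mean()
        assert frac[8] <= frac[1]


class TestCrCorrelation:
    def _session(self, cr_gain):
        sched = six_block_schedule(2, 50)
        trials = make_schedule(sched, stage_rng(9, "s"))
        rng = stage_rng(9, "cr")
        cr_flags = np.zeros(len(trials), bool)
        block2 = trials.df["block_id"].to_numpy() == 2
        cr_flags[block2] = rng.random(block2.sum()) < 0.5
        cell = CellParams("u0", np.full(6, 4.0), np.full(6, 2.0), "Non-S", True)
        spikes = simulate_spikes(cell, trials, stage_rng(9, "x"), sched,
                                 cr_flags=cr_flags, cr_gain=cr_gain)
        labels = np.where(cr_flags, "CR", "noCR")
        return Unit("u0", spikes), trials, labels, sched

    def test_insufficient_trials_not_computable(self):
        unit, trials, labels, sched = self._session(1.0)
        labels = labels.copy()
        labels[:] = "noCR"  # zero CR trials anywhere
        res = cr_correlation(unit, trials, labels, 2, sched, AnalysisConfig(),
                             stage_rng(0, "t"))
        assert not res.computable

    def test_cr_locked_rate_doubling_detected(self):
        unit, trials, labels, sched = self._session(2.0)
        cfg = AnalysisConfig(n_permutations=500)
        hits = sum(
            cr_correlation(unit, trials, labels, 2, sched, cfg, stage_rng(s, "t")).selective_trial
            for s in range(10))
        assert hits >= 8

    def test_cr_independent_firing_rarely_selective(self):
        unit, trials, labels, sched = self._session(1.0)
        cfg = AnalysisConfig(n_permutations=500)
        hits = sum(
            cr_correlation(unit, trials, labels, 2, sched, cfg, stage_rng(s, "t")).selective_trial
            for s in range(20))
        assert hits <= 4
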