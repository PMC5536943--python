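"""Generator properties: schedule layout, category construction, Poisson law."""

import numpy as np
import pytest

from lecpipe._rng import stage_rng
from lecpipe.synth import (
    CATEGORIES,
    CellParams,
    CrBehaviorConfig,
    PopulationConfig,
    category_flags,
    make_schedule,
    sample_population,
    simulate_emg,
    simulate_spikes,
)
from lecpipe.types import BlockSpec, SessionSchedule, TrialTable, ValidationError

from conftest import six_block_schedule


class TestMakeSchedule:
    def test_default_schedule_has_210_trials(self):
        tt = make_schedule(SessionSchedule(), stage_rng(0, "s"))
        assert len(tt) == 210

    def test_itis_within_bounds_and_sequential(self):
        sched = SessionSchedule()
        tt = make_schedule(sched, stage_rng(3, "s"))
        us_end = tt.us_equivalent_s() + sched.us_duration_s
        cs = tt.df["cs_onset_s"].to_numpy()
        gaps = np.concatenate([[cs[0]], cs[1:] - us_end[:-1]])
        assert gaps.min() >= sched.iti_min_s - 1e-9
        assert gaps.max() <= sched.iti_max_s + 1e-9

    def test_single_trial_block(self):
        sched = SessionSchedule(blocks=(BlockSpec(1, "auditory", 1, False, 1),),
                                iti_min_s=10, iti_max_s=12)
        tt = make_schedule(sched, stage_rng(0, "s"))
        assert len(tt) == 1

    def test_fixed_seed_is_deterministic(self):
        a = make_schedule(SessionSchedule(), stage_rng(9, "s"))
        b = make_schedule(SessionSchedule(), stage_rng(9, "s"))
        assert a == b


class TestSamplePopulation:
    def test_non_selective_cells_have_flat_rates(self):
        cfg = PopulationConfig(n_cells=10, category_proportions={"Non-S": 1.0}, effect_size=1.0)
        cells = sample_population(cfg, stage_rng(0, "p"))
        for c in cells:
            assert np.ptp(c.baseline_rate_hz) == 0

    def test_environment_cells_differ_only_across_boxes(self):
        sched = six_block_schedule(10, 12)
        cfg = PopulationConfig(n_cells=20, category_proportions={"E": 1.0}, effect_size=0.5)
        cells = sample_population(cfg, stage_rng(1, "p"), sched)
        boxes = np.array([b.box for b in sched.blocks])
        for c in cells:
            r = c.baseline_rate_hz
            hi, lo = r[boxes == 2].mean(), r[boxes == 1].mean()
            assert np.ptp(r[boxes == 1]) == 0 and np.ptp(r[boxes == 2]) == 0
            assert max(hi, lo) / min(hi, lo) == pytest.approx(1.5)

    def test_category_mix_matches_multinomial(self):
        cfg = PopulationConfig(n_cells=1000,
                               category_proportions={"R": 0.5, "Non-S": 0.5})
        cells = sample_population(cfg, stage_rng(2, "p"))
        frac_r = np.mean([c.category_label == "R" for c in cells])
        sd = np.sqrt(0.25 / 1000)
        assert abs(frac_r - 0.5) < 3 * sd

    def test_category_faithfulness(self):
        """Unequal generating rates appear exactly for the labeled contrasts."""
        sched = six_block_schedule(10, 12)
        cfg = PopulationConfig(n_cells=40, effect_size=1.0)
        cells = sample_population(cfg, stage_rng(4, "p"), sched)
        blocks = sched.blocks
        for c in cells:
            r = {b.block_id: rate for b, rate in zip(blocks, c.baseline_rate_hz)}
            r_diff = any(not np.isclose(r[a], r[p]) for a, p in [(1, 2), (3, 4), (5, 6)])
            m_diff = not np.isclose(r[1] + r[2], r[5] + r[6])
            e_diff = not np.isclose(r[1] + r[2], r[3] + r[4])
            flags = category_flags(c.category_label)
            assert (r_diff, m_diff, e_diff) == flags


class TestSimulateSpikes:
    def test_zero_rate_gives_empty_train(self):
        sched = six_block_schedule(2, 2)
        tt = make_schedule(sched, stage_rng(0, "s"))
        cell = CellParams("u0", np.zeros(6), np.ones(6), "Non-S", False)
        assert len(simulate_spikes(cell, tt, stage_rng(0, "x"), sched)) == 0

    def test_poisson_count_law_in_iti_window(self):
        """Mean spike count over replicates matches rate x duration."""
        sched = six_block_schedule(2, 2)
        tt = make_schedule(sched, stage_rng(1, "s"))
        cell = CellParams("u0", np.full(6, 2.0), np.ones(6), "Non-S", False)
        rng = stage_rng(5, "x")
        cs0 = tt.df["cs_onset_s"].iloc[0]
        counts = []
        for _ in range(500):
            t = simulate_spikes(cell, tt, rng, sched)
            counts.append(np.sum((t >= cs0 - 9.0) & (t < cs0)))
        mean, se = np.mean(counts), np.std(counts) / np.sqrt(500)
        assert abs(mean - 18.0) < 3 * max(se, 1e-9)

    def test_phasic_gain_scales_trial_window_rate(self):
        sched = six_block_schedule(2, 50)
        tt = make_schedule(sched, stage_rng(2, "s"))
        gains = np.ones(6)
        gains[1] = 5.0  # block 2 = auditory paired in box 1
        cell = CellParams("u0", np.full(6, 4.0), gains, "Non-S", True)
        t = simulate_spikes(cell, tt, stage_rng(6, "x"), sched)
        sub = tt.block_trials(2)
        cs = sub["cs_onset_s"].to_numpy()
        trial_rate = np.mean([np.sum((t >= a) & (t < a + 0.6)) / 0.6 for a in cs])
        iti_rate = np.mean([np.sum((t >= a - 9) & (t < a)) / 9.0 for a in cs])
        assert trial_rate / iti_rate == pytest.approx(5.0, rel=0.25)


class TestSimulateEmg:
    def test_zero_probability_gives_no_crs(self):
        sched = six_block_schedule(2, 2, emg_rate_hz=1000.0)
        tt = make_schedule(sched, stage_rng(0, "s"))
        crc = CrBehaviorConfig(cr_probability_paired=0.0, cr_probability_alone=0.0)
        _, flags = simulate_emg(tt, crc, sched, stage_rng(0, "e"))
        assert flags.sum() == 0

    def test_baseline_variance_matches_band_fraction(self):
        """Band-passing white noise keeps the in-band share of total power."""
        sched = six_block_schedule(2, 2, emg_rate_hz=10_000.0)
        tt = make_schedule(sched, stage_rng(1, "s"))
        crc = CrBehaviorConfig(cr_probability_paired=0.0, cr_probability_alone=0.0,
                               baseline_noise_sd=2.0)
        emg, _ = simulate_emg(tt, crc, sched, stage_rng(1, "e"))
        band_fraction = (min(crc.band_high_hz, 0.45 * sched.emg_rate_hz)
                         - crc.band_low_hz) / (sched.emg_rate_hz / 2)
        expected_var = crc.baseline_noise_sd ** 2 * band_fraction
        assert emg.samples.var() == pytest.approx(expected_var, rel=0.05)

    def test_subunity_burst_warns(self):
        with pytest.warns(UserWarning):
            CrBehaviorConfig(cr_burst_amplitude=0.5)

    def test_iti_bounds_validation(self):
        with pytest.raises(ValidationError):
            SessionSchedule(iti_min_s=30, iti_max_s=20)
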