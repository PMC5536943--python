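"""State-vector correlation analyses: block pairs, ITI matrix, similarity."""

import numpy as np
import pytest

from lecpipe._rng import stage_rng
from lecpipe.ensemble import (
    block_pair_comparison,
    fit_trend,
    iti_correlation_matrix,
    normalize_rows,
    pearson_r,
    session_sliding_trend,
    similarity_scores,
    similarity_scores_from_matrix,
    transition_type,
)
from lecpipe.synth import GeneratorConfig, PopulationConfig, generate_session
from lecpipe.types import AnalysisConfig, ValidationError

from conftest import six_block_schedule


class TestPearson:
    def test_affine_relation_gives_unity(self):
        x = np.array([1.0, 2, 3, 4])
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        assert pearson_r(np.array([1.0, 2, 3]), np.array([1.0, 3, 2])) == pytest.approx(0.5)

    def test_constant_vector_undefined(self):
        with pytest.warns(UserWarning):
            assert np.isnan(pearson_r(np.array([1.0, 1, 1]), np.array([1.0, 2, 3])))


class TestNormalization:
    def test_row_max_is_one_and_idempotent(self):
        rng = np.random.default_rng(0)
        m = rng.random((10, 6)) * 5
        m[3] = 0.0  # silent cell is dropped
        norm, keep = normalize_rows(m)
        assert norm.shape == (9, 6)
        assert np.allclose(norm.max(axis=1), 1.0)
        again, keep2 = normalize_rows(norm)
        assert np.allclose(again, norm) and keep2.all()


class TestBlockPairComparison:
    def test_emits_40_r_values_per_category(self, small_session):
        spikes, trials, schedule, _ = small_session
        cfg = AnalysisConfig(n_repeats=20)
        bp = block_pair_comparison(spikes, trials, schedule, cfg, "trial", seed=2)
        assert (bp.groupby("category").size() == 40).all()

    def test_modality_coded_population_ordering(self):
        """Pure modality code: modality pairs decorrelate most, matched-block
        controls stay highest."""
        sched = six_block_schedule(10, 12)
        gen = GeneratorConfig(schedule=sched, population=PopulationConfig(
            n_cells=40, rate_median_hz=3.0, effect_size=1.5,
            category_proportions={"M": 0.6, "M+E": 0.4}, responsive_fraction=0.0),
            with_emg=False)
        spikes, trials, _, schedule, _ = generate_session(gen, seed=13)
        cfg = AnalysisConfig(n_repeats=10)
        bp = block_pair_comparison(spikes, trials, schedule, cfg, "iti", seed=3)
        mean_r = bp.groupby("category")["r"].mean()
        assert mean_r["Modality"] < mean_r["Environment"]
        assert mean_r["Environment"] < mean_r["None"]
        assert mean_r["All"] < mean_r["None"]

    def test_too_few_trials_errors(self, small_session):
        spikes, trials, schedule, _ = small_session
        with pytest.raises(ValidationError):
            block_pair_comparison(spikes, trials, schedule, AnalysisConfig(),
                                  "trial", seed=0, n_select=50)


class TestItiMatrix:
    def test_shape_symmetry_and_unit_diagonal(self, small_session):
        spikes, trials, schedule, _ = small_session
        cfg = AnalysisConfig()
        m = iti_correlation_matrix(spikes, trials, schedule, cfg,
                                   stage_rng(0, "m"), n_subsample=len(spikes))
        assert m.shape == (len(trials), len(trials))
        assert np.allclose(m, m.T, equal_nan=True)
        assert np.allclose(np.diag(m), 1.0)

    def test_box_keyed_block_structure(self, blocked_session):
        """Within-box ITI pairs correlate more than cross-box pairs."""
        spikes, trials, schedule, _ = blocked_session
        m = iti_correlation_matrix(spikes, trials, schedule, AnalysisConfig(),
                                   stage_rng(1, "m"), n_subsample=len(spikes))
        box = np.array([schedule.block(int(b)).box
                        for b in trials.df["block_id"]])
        same = box[:, None] == box[None, :]
        off = ~np.eye(len(box), dtype=bool)
        assert np.nanmean(m[same & off]) > np.nanmean(m[~same]) + 0.1


class TestSimilarityScores:
    def test_transition_typing(self, blocked_session):
        _, _, schedule, _ = blocked_session
        types = [transition_type(schedule.blocks[i], schedule.blocks[i + 1])
                 for i in range(5)]
        assert types == ["R", "E", "R", "E+M", "R"]

    def test_box_step_change_pattern(self, blocked_session):
        """Tonic steps at box changes: between << within at E and E+M but not
        R transitions, and the double change decorrelates more."""
        spikes, trials, schedule, _ = blocked_session
        cfg = AnalysisConfig(n_repeats=5, n_subsample_cells_ensemble=30)
        ss = similarity_scores(spikes, trials, schedule, cfg, seed=4)
        agg = ss.groupby("type")[["within", "between"]].mean()
        assert agg.loc["E", "between"] < agg.loc["E", "within"] - 0.2
        assert agg.loc["E+M", "between"] < agg.loc["E+M", "within"] - 0.2
        assert agg.loc["E+M", "between"] < agg.loc["E", "between"]
        r = agg.loc["R"]
        assert abs(r["within"] - r["between"]) < 0.2

    def test_short_blocks_rejected(self, small_session):
        spikes, trials, schedule, _ = small_session
        m = np.eye(len(trials))
        with pytest.raises(ValidationError):
            similarity_scores_from_matrix(m, schedule)


class TestTrend:
    def test_linear_series_r2_one(self):
        res = fit_trend("E+M", np.arange(10) * 0.03 + 0.1)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(0.03)

    def test_constant_series_flat(self):
        res = fit_trend("E", np.full(8, 0.2))
        assert res.slope == 0.0 and res.r_squared == 0.0

    def test_growing_effect_across_sessions_detected(self):
        """Cells from later sessions carry a bigger box/modality step, so the
        transition magnitude grows across the sliding cell window."""
        sched = six_block_schedule(20, 25)
        gen = GeneratorConfig(schedule=sched, population=PopulationConfig(
            n_cells=60, rate_median_hz=3.0, effect_size=1.0,
            category_proportions={"M+E": 1.0}, responsive_fraction=0.0,
            n_sessions=6, effect_scale_by_session=tuple(0.15 + 0.17 * i for i in range(6))),
            with_emg=False)
        spikes, trials, _, schedule, _ = generate_session(gen, seed=29)
        cfg = AnalysisConfig()
        trend = session_sliding_trend(spikes, trials, schedule, cfg,
                                      window=30, step=5, seed=5)
        em = trend.set_index("transition_type").loc["E+M"]
        assert em["slope"] > 0
        assert em["r_squared"] > 0.5
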