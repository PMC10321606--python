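import numpy as np
import pandas as pd
import pytest
from numpy.testing import assert_allclose

from artidelta.delta_extraction import DeltaTrace
from artidelta.epoching import (
    ConditionAverage,
    EmptyWindowError,
    ExclusionConfig,
    GridMismatchError,
    LockError,
    WindowPolicy,
    average_condition,
    build_analysis_matrix,
    epoch_trace,
    filter_trials,
)
from artidelta.synthetic_data import EARLY, LATE, TrialEvents


def toy_events_table():
    base = dict(
        condition=EARLY,
        question_onset=0.0,
        critical_word_onset=1.0,
        question_offset=3.0,
        response_offset=9.9,
        onset_phoneme="k",
    )
    rows = [
        dict(base, participant_id=1, item_id=1, response_onset=3.5,
             correct=False, hesitation=False),
        dict(base, participant_id=1, item_id=2, response_onset=8.2,  # RT 5.2 s
             correct=True, hesitation=False),
        dict(base, participant_id=1, item_id=3, response_onset=3.5,
             correct=True, hesitation=True),
        dict(base, participant_id=1, item_id=4, response_onset=3.5,
             correct=True, hesitation=False),
    ]
    return pd.DataFrame(rows)


class TestFilterTrials:
    def test_toy_table_stage_counts(self):
        kept, report = filter_trials(toy_events_table(), ExclusionConfig())
        assert len(kept) == 1
        assert [s["removed"] for s in report.stages] == [2, 1, 0]
        assert [s["denominator"] for s in report.stages] == [4, 2, 1]

    def test_empty_config_keeps_everything(self):
        cfg = ExclusionConfig(
            max_rt=1e9, drop_incorrect=False, drop_hesitation=False,
            excluded_phonemes=frozenset(),
        )
        table = toy_events_table()
        kept, report = filter_trials(table, cfg)
        assert len(kept) == len(table)
        assert report.n_kept == report.n_input

    def test_phoneme_stage(self):
        table = toy_events_table()
        table.loc[3, "onset_phoneme"] = "p"  # the otherwise-clean trial
        kept, report = filter_trials(table, ExclusionConfig())
        assert len(kept) == 0
        assert report.stages[2]["removed"] == 1

    def test_unknown_phoneme_warns_and_keeps(self):
        table = toy_events_table()
        table.loc[3, "onset_phoneme"] = "q#"
        with pytest.warns(UserWarning, match="unknown onset phoneme"):
            kept, _ = filter_trials(table, ExclusionConfig())
        assert len(kept) == 1

    def test_participant_subset(self):
        table = toy_events_table()
        kept, report = filter_trials(
            table, ExclusionConfig(participant_subset=[99])
        )
        assert report.n_input == 0 and len(kept) == 0

    def test_final_set_independent_of_stage_order(self):
        # order affects reported denominators, never membership
        table = toy_events_table()
        kept, _ = filter_trials(table, ExclusionConfig())
        ok = (
            table["correct"]
            & ~table["hesitation"]
            & ((table["response_onset"] - table["question_offset"]) <= 5.0)
            & ~table["onset_phoneme"].isin(ExclusionConfig().excluded_phonemes)
        )
        assert set(kept["item_id"]) == set(table[ok]["item_id"])


def make_trace(timestamps, values, fps=100.0, participant=1, item=1, cond=EARLY):
    return DeltaTrace(
        timestamps=np.asarray(timestamps, float),
        values=np.asarray(values, float),
        frame_rate_hz=fps, normalization="none",
        participant_id=participant, item_id=item, condition=cond,
    )


def make_events(**kw):
    d = dict(
        participant_id=1, item_id=1, condition=EARLY,
        question_onset=0.0, critical_word_onset=0.5, question_offset=1.0,
        response_onset=1.4, response_offset=1.9,
        correct=True, hesitation=False, onset_phoneme="k",
    )
    d.update(kw)
    return TrialEvents(**d)


class TestEpochTrace:
    def test_grid_identity_when_already_sampled_on_grid(self):
        # trace timestamps k/100 relative to lock at t=1.0 land on the grid
        ts = np.arange(0, 200) / 100.0
        vals = np.sin(ts)
        ep = epoch_trace(make_trace(ts, vals), make_events(), "TL1")
        # every grid point coincides with a sample, so interpolation is exact
        assert_allclose(
            ep.values[ep.valid], np.sin(ep.grid_times[ep.valid] + 1.0), atol=1e-9
        )

    def test_grid_contains_zero_and_tl3_definition(self):
        ts = np.arange(0, 300) / 100.0
        ep = epoch_trace(make_trace(ts, ts), make_events(), "TL3")
        assert 0.0 in ep.grid_times
        # grid 0 equals response onset on the trial clock; trace value there
        # equals the trial-clock time of the lock
        k0 = int(np.flatnonzero(np.isclose(ep.grid_times, 0.0))[0])
        assert ep.values[k0] == pytest.approx(1.4, abs=1e-9)

    def test_piecewise_linear_interpolation_analytic(self):
        # ramp y = 3t + 2 sampled irregularly relative to the grid
        ts = np.array([0.003, 0.52, 0.9, 1.31, 2.07])
        vals = 3.0 * ts + 2.0
        ep = epoch_trace(make_trace(ts, vals), make_events(), "TL1")
        inside = ep.valid
        assert_allclose(
            ep.values[inside], 3.0 * (ep.grid_times[inside] + 1.0) + 2.0,
            atol=1e-9,
        )

    def test_invalid_outside_span(self):
        ts = np.arange(50, 150) / 100.0
        ep = epoch_trace(make_trace(ts, np.ones_like(ts)), make_events(), "TL1")
        assert not ep.valid[0] or ep.grid_times[0] >= -0.51
        assert np.isnan(ep.values[~ep.valid]).all()

    def test_lock_beyond_span_errors(self):
        ts = np.arange(0, 30) / 100.0  # span 0-0.29 s; response at 1.4 s
        with pytest.raises(LockError):
            epoch_trace(make_trace(ts, ts), make_events(), "TL3")

    def test_unknown_lock(self):
        ts = np.arange(0, 30) / 100.0
        with pytest.raises(ValueError, match="lock"):
            epoch_trace(make_trace(ts, ts), make_events(), "TL9")


class TestAverageCondition:
    def epoch(self, offset, participant=1, item=1, value=1.0, n=100):
        ts = np.arange(n) / 100.0 + offset
        return epoch_trace(
            make_trace(ts, np.full(n, value), participant=participant, item=item),
            make_events(participant_id=participant, item_id=item),
            "TL1",
        )

    def test_single_epoch_mean_is_identity(self):
        ep = self.epoch(0.0)
        avg = average_condition([ep])
        assert_allclose(avg.mean_values[avg.n_trials > 0],
                        ep.values[ep.valid], atol=1e-12)
        assert (avg.n_trials[avg.n_trials > 0] == 1).all()

    def test_two_epochs_mean_and_counts(self):
        e1 = self.epoch(0.0, item=1, value=2.0)
        e2 = self.epoch(0.0, item=2, value=4.0)
        avg = average_condition([e1, e2])
        shared = avg.n_trials == 2
        assert shared.any()
        assert_allclose(avg.mean_values[shared], 3.0)

    def test_union_grid_counts_at_edges(self):
        e1 = self.epoch(0.0, item=1, n=100)
        e2 = self.epoch(0.5, item=2, n=100)  # starts 0.5 s later, ends later
        avg = average_condition([e1, e2])
        assert avg.n_trials.max() == 2
        assert avg.n_trials[0] == 1 and avg.n_trials[-1] == 1

    def test_mean_bounded_by_contributors(self, rng):
        eps = [self.epoch(0.0, item=i, value=float(v))
               for i, v in enumerate(rng.uniform(1, 9, size=5))]
        avg = average_condition(eps)
        vals = [e.values for e in eps]
        lo = np.min(vals, axis=0)
        hi = np.max(vals, axis=0)
        inside = avg.n_trials == 5
        assert np.all(avg.mean_values[inside] >= lo[inside] - 1e-12)
        assert np.all(avg.mean_values[inside] <= hi[inside] + 1e-12)

    def test_mixed_participants_rejected(self):
        with pytest.raises(GridMismatchError):
            average_condition([self.epoch(0.0), self.epoch(0.0, participant=2)])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_condition([])


def test_all_generated_trials_cover_question_offset():
    # 23 early-planning epochs: every recording spans question offset, so
    # the TL1 grid point 0 counts all 23 trials
    from artidelta.pipeline_io import events_from_row
    from artidelta.synthetic_data import GeneratorConfig, generate_dataset

    cfg = GeneratorConfig(
        n_participants=1, image_width_px=64,
        n_trials_per_condition={EARLY: 23, LATE: 1},
    )
    kinematics, events = generate_dataset(cfg, render=False)
    epochs = []
    for kin, (_, row) in zip(kinematics, events.iterrows()):
        if row["condition"] == EARLY:
            epochs.append(epoch_trace(kin.as_delta_trace(),
                                      events_from_row(row), "TL1"))
    avg = average_condition(epochs)
    k0 = int(np.flatnonzero(np.isclose(avg.grid_times, 0.0))[0])
    assert avg.n_trials[k0] == 23


def make_average(participant, condition, t_lo, t_hi, fps=100.0, value=1.0,
                 n_trials=5):
    k_lo, k_hi = int(round(t_lo * fps)), int(round(t_hi * fps))
    width = k_hi - k_lo + 1
    return ConditionAverage(
        participant_id=participant, condition=condition, lock="TL1",
        grid_times=np.arange(k_lo, k_hi + 1) / fps,
        mean_values=np.full(width, value),
        n_trials=np.full(width, n_trials, dtype=int),
        k_start=k_lo, frame_rate_hz=fps,
    )


class TestBuildAnalysisMatrix:
    def averages(self):
        return [
            make_average(1, EARLY, -1.0, 3.0), make_average(1, LATE, -1.0, 3.0),
            make_average(2, EARLY, -2.0, 2.0), make_average(2, LATE, -2.0, 2.0),
        ]

    def test_window_intersection(self):
        mats, times = build_analysis_matrix(self.averages(), "TL1")
        assert times[0] == pytest.approx(-1.0)
        assert times[-1] == pytest.approx(2.0)
        assert mats[EARLY].shape == (2, len(times))

    def test_min_trials_too_large(self):
        with pytest.raises(EmptyWindowError):
            build_analysis_matrix(self.averages(), "TL1",
                                  WindowPolicy(min_trials=99))

    def test_missing_condition_rejected(self):
        avs = self.averages()[:-1]
        with pytest.raises(ValueError, match="lacks"):
            build_analysis_matrix(avs, "TL1")

    def test_clip_applies(self):
        mats, times = build_analysis_matrix(
            self.averages(), "TL1", WindowPolicy(clip=(-0.5, 0.5))
        )
        assert times[0] >= -0.5 - 1e-9 and times[-1] <= 0.5 + 1e-9

    def test_window_then_average_commutes(self):
        # timepoint-wise operations: restricting first then stacking equals
        # stacking then restricting
        mats_full, times_full = build_analysis_matrix(self.averages(), "TL1")
        mats_clip, times_clip = build_analysis_matrix(
            self.averages(), "TL1", WindowPolicy(clip=(-0.5, 1.0))
        )
        sel = (times_full >= -0.5 - 1e-9) & (times_full <= 1.0 + 1e-9)
        assert_allclose(mats_clip[EARLY], mats_full[EARLY][:, sel])
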