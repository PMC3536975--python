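import numpy as np
import pytest

from covisa.simulate import (
    ALL_DIRECTIONS,
    COMMAND_DIRECTIONS,
    Direction,
    Hrf,
    NoiseModel,
    OnlineSynthesizer,
    ScanProtocol,
    Trial,
    CueSchedule,
    attention_regressors,
    build_cue_schedule,
    default_phantom,
    session_array,
    synthesize_session,
)


class TestCueSchedule:
    def test_default_protocol_gives_54_balanced_trials(self):
        sched = build_cue_schedule(ScanProtocol(), seed=7)
        assert len(sched.trials) == 54
        counts = sched.direction_counts()
        assert counts[Direction.CENTER] == 27
        assert all(counts[d] == 9 for d in COMMAND_DIRECTIONS)
        assert all(t.length_volumes == 5 for t in sched.trials)

    def test_directional_trials_separated_by_center(self):
        sched = build_cue_schedule(ScanProtocol(), seed=3)
        dirs = [t.direction for t in sched.trials]
        for a, b in zip(dirs, dirs[1:]):
            assert Direction.CENTER in (a, b)

    def test_deterministic_given_seed(self):
        p = ScanProtocol()
        assert build_cue_schedule(p, 11).trials == build_cue_schedule(p, 11).trials
        assert build_cue_schedule(p, 11).trials != build_cue_schedule(p, 12).trials

    def test_smallest_alternating_case(self):
        p = ScanProtocol(n_localizer=10, trial_len=5)
        sched = build_cue_schedule(p, seed=0)
        assert len(sched.trials) == 2
        assert sched.trials[0].direction == Direction.CENTER
        assert sched.trials[1].direction in COMMAND_DIRECTIONS

    def test_untileable_localizer_rejected(self):
        with pytest.raises(ValueError, match="tileable"):
            build_cue_schedule(ScanProtocol(n_localizer=272, trial_len=5), seed=0)

    def test_states_cover_localizer_exactly(self):
        p = ScanProtocol()
        sched = build_cue_schedule(p, seed=5)
        assert len(sched.states()) == p.n_localizer

    def test_gapped_trials_rejected(self):
        with pytest.raises(ValueError, match="tile"):
            CueSchedule((Trial(Direction.CENTER, 0, 5), Trial(Direction.UP, 6, 5)))

    def test_adjacent_directional_trials_rejected(self):
        with pytest.raises(ValueError, match="separated"):
            CueSchedule((Trial(Direction.UP, 0, 5), Trial(Direction.LEFT, 5, 5)))


class TestAttentionRegressors:
    def test_identity_kernel_reproduces_boxcar(self, toy_schedule, toy_protocol):
        hrf = Hrf(kernel=np.array([1.0]), lag_volumes=0)
        regs, ramp = attention_regressors(toy_schedule, hrf, toy_protocol.n_localizer)
        states = toy_schedule.states()
        for d in ALL_DIRECTIONS:
            box = np.array([1.0 if s == d else 0.0 for s in states])
            np.testing.assert_array_equal(regs[d], box)
        assert ramp[0] == 0.0 and ramp[-1] == 1.0

    def test_causality_zero_before_first_trial(self, hrf):
        p = ScanProtocol(n_localizer=30, trial_len=5)
        sched = build_cue_schedule(p, seed=2)
        regs, _ = attention_regressors(sched, hrf, p.n_localizer)
        for d in COMMAND_DIRECTIONS:
            first = next(t.start_volume for t in sched.trials if t.direction == d)
            assert np.all(regs[d][:first] == 0.0)

    def test_convolution_matches_discrete_oracle(self):
        # boxcar of length 5 starting at volume 10; kernel of length 12:
        # value at volume 14 is sum(kernel[0..4])
        kernel = np.linspace(1.0, 0.1, 12)
        hrf = Hrf(kernel=kernel, lag_volumes=0)
        trials = (
            Trial(Direction.CENTER, 0, 10),
            Trial(Direction.UP, 10, 5),
            Trial(Direction.CENTER, 15, 10),
        )
        sched = CueSchedule(trials)
        regs, _ = attention_regressors(sched, hrf, 25)
        assert regs[Direction.UP][14] == pytest.approx(kernel[:5].sum())
        # independent full-convolution oracle
        box = np.zeros(25)
        box[10:15] = 1.0
        oracle = np.convolve(box, kernel)[:25]
        np.testing.assert_allclose(regs[Direction.UP], oracle)


class TestSynthesis:
    def _small(self):
        p = ScanProtocol(n_localizer=20, n_control=10, matrix=(10, 10, 6))
        sched = build_cue_schedule(p, seed=0)
        ph = default_phantom(p.matrix)
        return p, sched, ph

    def test_null_signal_reproduces_baseline(self):
        p, sched, ph = self._small()
        flat = default_phantom(p.matrix, amplitude=0.0)
        script = [Direction.CENTER] * p.n_control
        vols, _ = session_array(p, sched, script, flat, Hrf.canonical(), NoiseModel())
        for v in range(p.n_total):
            np.testing.assert_array_equal(vols[..., v], flat.baseline)

    def test_fixed_seed_bit_identical(self):
        p, sched, ph = self._small()
        script = [Direction.UP] * p.n_control
        noise = NoiseModel(white_sd=5.0, drift_walk_sd=0.5, seed=9)
        v1, _ = session_array(p, sched, script, ph, Hrf.canonical(), noise)
        v2, _ = session_array(p, sched, script, ph, Hrf.canonical(), noise)
        np.testing.assert_array_equal(v1, v2)

    def test_plateau_matches_steady_state_convolution(self):
        # sustained attention long enough to plateau: value = baseline *
        # (1 + amplitude * sum(kernel))
        kernel = np.array([0.1, 0.3, 0.4, 0.2])
        hrf = Hrf(kernel=kernel, lag_volumes=2)
        p = ScanProtocol(n_localizer=10, n_control=20, matrix=(10, 10, 6))
        sched = build_cue_schedule(p, seed=0)
        ph = default_phantom(p.matrix, amplitude=0.02)
        script = [Direction.UP] * p.n_control
        vols, _ = session_array(p, sched, script, ph, hrf, NoiseModel())
        roi = ph.roi_indices(Direction.UP)[0]
        ijk = np.unravel_index(roi, p.matrix)
        base = ph.baseline[ijk]
        plateau = vols[ijk][-1]
        assert plateau == pytest.approx(base * (1 + 0.02 * kernel.sum()))

    def test_non_roi_voxels_constant_without_noise(self):
        p, sched, ph = self._small()
        script = [Direction.RIGHT] * p.n_control
        vols, _ = session_array(p, sched, script, ph, Hrf.canonical(), NoiseModel())
        any_roi = np.zeros(p.matrix, dtype=bool)
        for d in ALL_DIRECTIONS:
            any_roi |= ph.roi_amplitude[d] > 0
        quiet = vols[~any_roi]
        assert np.all(quiet == quiet[:, :1])

    def test_ground_truth_matches_schedule(self):
        p, sched, ph = self._small()
        script = [Direction.LEFT] * p.n_control
        _, truth = session_array(p, sched, script, ph, Hrf.canonical(), NoiseModel())
        assert truth.states[: p.n_localizer] == sched.states()
        assert truth.states[p.n_localizer :] == script

    def test_control_script_length_mismatch_rejected(self):
        p, sched, ph = self._small()
        with pytest.raises(ValueError, match="control_script"):
            synthesize_session(p, sched, [Direction.CENTER], ph, Hrf.canonical(), NoiseModel())

    def test_streaming_synthesizer_rejects_overrun(self):
        p, sched, ph = self._small()
        synth = OnlineSynthesizer(p, ph, Hrf.canonical(), NoiseModel())
        for _ in range(p.n_total):
            synth.next_volume(Direction.CENTER)
        with pytest.raises(ValueError, match="complete"):
            synth.next_volume(Direction.CENTER)


class TestHrf:
    def test_canonical_kernel_properties(self):
        h = Hrf.canonical(1.62)
        assert h.kernel[0] == pytest.approx(0.0, abs=1e-6)
        assert h.kernel.max() == pytest.approx(1.0)
        assert h.kernel.sum() > 0
        assert h.lag_volumes == int(np.argmax(h.kernel))

    def test_pure_delay_kernel(self):
        h = Hrf.pure_delay(3)
        assert h.kernel[3] == 1.0 and h.kernel[:3].sum() == 0.0

    def test_nonpositive_kernel_rejected(self):
        with pytest.raises(ValueError):
            Hrf(kernel=np.array([-1.0, 0.5]), lag_volumes=0)
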