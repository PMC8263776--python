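"""Change-point step counting: exactness, robustness, quality gate."""

import numpy as np
import pytest

from oligotrace.steps import (
    AcceptanceParams,
    StepCountTable,
    StepFitParams,
    accept_trace,
    count_distribution,
    fit_steps,
)
from oligotrace.synthetic import SimConfig, resolvable_step_count, simulate_traces
from oligotrace.traces import BleachTrace


def staircase(levels, frames_per_level=10) -> BleachTrace:
    values = np.concatenate([np.full(frames_per_level, float(lv)) for lv in levels])
    return BleachTrace(values=values, frame_interval=0.1, spot_id="stair")


class TestFitSteps:
    def test_noiseless_staircase_recovered_exactly(self):
        trace = staircase([500, 400, 300, 200, 100, 0])
        fit = fit_steps(trace, StepFitParams(monotone=True))
        assert fit.n_steps == 5
        assert fit.change_points == (10, 20, 30, 40, 50)
        np.testing.assert_allclose(fit.levels, [500, 400, 300, 200, 100, 0], atol=1e-9)

    def test_flat_trace_has_no_steps(self):
        fit = fit_steps(BleachTrace(values=np.full(50, 120.0), frame_interval=0.1, spot_id=0))
        assert fit.n_steps == 0
        assert fit.levels == (120.0,)

    def test_short_trace_rejected_as_not_evaluable(self):
        with pytest.raises(ValueError, match="frames"):
            fit_steps(BleachTrace(values=np.zeros(5), frame_interval=0.1, spot_id=0))

    def test_offset_invariance(self):
        rng = np.random.default_rng(1)
        values = np.concatenate([np.full(30, 200.0), np.full(30, 100.0), np.full(30, 0.0)])
        values = values + rng.normal(0, 10, len(values))
        t1 = BleachTrace(values=values, frame_interval=0.1, spot_id=0)
        t2 = BleachTrace(values=values + 5000.0, frame_interval=0.1, spot_id=0)
        f1, f2 = fit_steps(t1), fit_steps(t2)
        assert f1.change_points == f2.change_points
        np.testing.assert_allclose(np.asarray(f2.levels) - np.asarray(f1.levels), 5000.0, atol=1e-9)

    def test_noiseless_simulated_traces_counted_exactly(self):
        cfg = SimConfig(seed=10, n_subunits=4, p_fluor=0.67, noise_sd=0.0)
        truth, traces = simulate_traces(cfg, n_visible=200)
        spots = {s.spot_id: s for s in truth}
        for trace in traces:
            fit = fit_steps(trace)
            assert fit.n_steps == resolvable_step_count(spots[trace.spot_id], cfg)

    def test_noisy_accuracy_at_snr_five(self):
        cfg = SimConfig(seed=11, n_subunits=2, p_fluor=0.67, noise_sd=20.0, unit_intensity=100.0)
        truth, traces = simulate_traces(cfg, n_visible=300)
        spots = {s.spot_id: s for s in truth}
        correct = sum(
            fit_steps(t).n_steps == resolvable_step_count(spots[t.spot_id], cfg) for t in traces
        )
        assert correct / len(traces) >= 0.95

    def test_accuracy_degrades_monotonically_with_noise(self):
        cfg0 = SimConfig(seed=12, n_subunits=2, p_fluor=0.67, noise_sd=0.0)
        truth, clean = simulate_traces(cfg0, n_visible=150)
        spots = {s.spot_id: s for s in truth}
        rng = np.random.default_rng(99)
        noise = [rng.standard_normal(len(t.values)) for t in clean]
        rates = []
        for sd in (0.0, 10.0, 20.0, 35.0, 50.0):
            correct = 0
            for t, z in zip(clean, noise):
                noisy = BleachTrace(values=t.values + sd * z, frame_interval=t.frame_interval,
                                    spot_id=t.spot_id)
                correct += fit_steps(noisy).n_steps == resolvable_step_count(spots[t.spot_id], cfg0)
            rates.append(correct / len(clean))
        assert all(a >= b - 1e-12 for a, b in zip(rates, rates[1:]))

    def test_monotone_mode_removes_upward_blip(self):
        values = np.concatenate([np.full(30, 100.0), np.full(30, 0.0)])
        values[15] += 100.0  # one-frame spurious blip
        trace = BleachTrace(values=values, frame_interval=0.1, spot_id=0)
        fit = fit_steps(trace, StepFitParams(monotone=True, merge_fraction=0.0))
        assert all(np.diff(fit.levels) < 0)


class TestAcceptTrace:
    def test_clean_two_step_trace_accepted(self):
        fit = accept_trace(fit_steps(staircase([200, 100, 0])))
        assert fit.accepted and fit.rejection_reason is None
        assert fit.n_steps == 2

    def test_too_many_steps_rejected(self):
        fit = accept_trace(fit_steps(staircase([500, 400, 300, 200, 100, 0])),
                           AcceptanceParams(k_max=4))
        assert not fit.accepted
        assert "K_max" in fit.rejection_reason

    def test_non_terminal_trace_rejected(self):
        fit = accept_trace(fit_steps(staircase([300, 200, 100])))  # never reaches 0
        assert not fit.accepted
        assert "non-terminal" in fit.rejection_reason

    def test_outsize_step_flagged_as_coincident(self):
        # steps 100, 100, 260: largest is 2.6x the median step
        fit = accept_trace(fit_steps(staircase([460, 360, 260, 0], frames_per_level=20)))
        assert not fit.accepted
        assert "coincident" in fit.rejection_reason

    def test_noiseless_tetramer_rejection_rate_low(self):
        cfg = SimConfig(seed=13, n_subunits=4, p_fluor=0.67, noise_sd=0.0)
        _, traces = simulate_traces(cfg, n_visible=400)
        rejected = sum(not accept_trace(fit_steps(t)).accepted for t in traces)
        assert rejected / len(traces) < 0.10


class TestCountDistribution:
    def test_counts_accepted_fits(self):
        fits = [accept_trace(fit_steps(staircase([100 * k - 100 * i for i in range(k + 1)])))
                for k in (1, 2, 2, 1)]
        table = count_distribution(fits)
        assert table.counts == {1: 2, 2: 2}
        assert table.total_spots == 4
        assert table.frequency(1) == table.frequency(2) == 0.5

    def test_single_fit(self):
        fit = accept_trace(fit_steps(staircase([300, 200, 100, 0])))
        table = count_distribution([fit])
        assert table.counts == {3: 1}

    def test_no_accepted_fits_is_an_error(self):
        flat = fit_steps(BleachTrace(values=np.zeros(20), frame_interval=0.1, spot_id=0))
        with pytest.raises(ValueError, match="accepted"):
            count_distribution([accept_trace(flat)])

    def test_table_invariants_enforced(self):
        with pytest.raises(ValueError):
            StepCountTable(counts={1: 3, 2: 2}, total_spots=4)
        with pytest.raises(ValueError):
            StepCountTable(counts={0: 1}, total_spots=1)
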