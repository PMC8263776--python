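"""Generator-level checks: distributions, determinism, conservation."""

import numpy as np
import pytest
from scipy import stats

from oligotrace.synthetic import (
    ColocPanelConfig,
    ColocTruth,
    FretGeometry,
    FretTruth,
    SimConfig,
    render_movie,
    resolvable_step_count,
    simulate_coloc_panel,
    simulate_fret_pair,
    simulate_spot_population,
)
from tests.conftest import enumeration_pmf


class TestSpotPopulation:
    def test_full_maturation_forces_all_subunits_fluorescent(self):
        cfg = SimConfig(seed=0, n_subunits=2, p_fluor=1.0, n_spots=50)
        truth, traces = simulate_spot_population(cfg)
        assert len(truth) == 50
        assert all(s.n_fluorescent == 2 for s in truth)
        assert len(traces) == 50

    def test_fluorophore_counts_follow_binomial(self):
        cfg = SimConfig(
            seed=42, n_subunits=4, p_fluor=0.67, n_spots=10_000, noise_sd=0.0,
            image_shape=(2200, 2200),
        )
        truth, _ = simulate_spot_population(cfg, include_dark=True)
        counts = np.bincount([s.n_fluorescent for s in truth], minlength=5)
        # oracle: exact PMF from enumerating the 2^4 on/off configurations
        p_visible = 1.0 - (1.0 - 0.67) ** 4
        probs = [(1 - 0.67) ** 4] + [
            enumeration_pmf(4, 0.67, k) * p_visible for k in (1, 2, 3, 4)
        ]
        res = stats.chisquare(counts, f_exp=np.array(probs) * 10_000)
        assert res.pvalue > 0.01

    def test_monomer_visibility_matches_p(self):
        cfg = SimConfig(seed=7, n_subunits=1, p_fluor=0.5, n_spots=1000, image_shape=(700, 700))
        truth, _ = simulate_spot_population(cfg)
        frac = sum(s.visible for s in truth) / len(truth)
        se = np.sqrt(0.5 * 0.5 / 1000)
        assert abs(frac - 0.5) <= 3 * se

    def test_bleach_time_mean_matches_exponential(self):
        cfg = SimConfig(
            seed=3, n_subunits=1, p_fluor=1.0, n_spots=10_000, bleach_mean_time=4.0,
            image_shape=(2200, 2200),
        )
        truth, _ = simulate_spot_population(cfg)
        times = np.array([s.bleach_times[0] for s in truth])
        assert abs(times.mean() - 4.0) / 4.0 < 0.02

    def test_same_seed_bit_identical(self):
        cfg = SimConfig(seed=5, n_subunits=2, p_fluor=0.67, n_spots=40, noise_sd=3.0)
        t1, tr1 = simulate_spot_population(cfg)
        t2, tr2 = simulate_spot_population(cfg)
        assert t1.spots == t2.spots
        for a, b in zip(tr1, tr2):
            np.testing.assert_array_equal(a.values, b.values)

    def test_positions_respect_min_separation(self):
        cfg = SimConfig(seed=9, n_spots=60, min_spot_separation=8.0, image_shape=(128, 128))
        truth, _ = simulate_spot_population(cfg)
        pos = np.array([s.position for s in truth])
        d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        assert d2.min() >= 8.0**2

    @pytest.mark.parametrize(
        "field,value",
        [("p_fluor", 1.5), ("n_subunits", 0), ("noise_sd", -1.0), ("frame_interval", 0.0)],
    )
    def test_invalid_config_names_the_field(self, field, value):
        with pytest.raises(ValueError, match=field):
            SimConfig(**{field: value})

    def test_dark_spots_excluded_unless_requested(self):
        cfg = SimConfig(seed=1, n_subunits=1, p_fluor=0.3, n_spots=200, image_shape=(256, 256))
        truth, traces = simulate_spot_population(cfg)
        assert len(traces) == sum(s.visible for s in truth) < 200
        _, all_traces = simulate_spot_population(cfg, include_dark=True)
        assert len(all_traces) == 200


class TestRenderMovie:
    def test_unbleached_spot_gives_identical_frames(self):
        cfg = SimConfig(seed=2, n_subunits=1, p_fluor=1.0, n_spots=1, noise_sd=0.0,
                        bleach_mean_time=1e6, n_frames=20, image_shape=(32, 32))
        truth, _ = simulate_spot_population(cfg)
        movie = render_movie(truth, cfg)
        for t in range(1, movie.n_frames):
            np.testing.assert_allclose(movie.data[t], movie.data[0], rtol=0, atol=1e-12)

    def test_single_bleach_is_single_downward_step(self):
        from oligotrace.synthetic import SpotTruth, SpotTruthTable

        cfg = SimConfig(seed=2, n_subunits=1, p_fluor=1.0, n_spots=1, noise_sd=0.0,
                        n_frames=50, image_shape=(32, 32))
        spot = SpotTruth(spot_id=0, position=(16.0, 16.0), n_fluorescent=1,
                         bleach_times=(10 * cfg.frame_interval - 1e-9,))
        movie = render_movie(SpotTruthTable(spots=(spot,), config=cfg), cfg)
        integrated = movie.data.sum(axis=(1, 2))
        diffs = np.diff(integrated)
        assert np.argmin(diffs) == 9  # drop between frame 9 and 10
        assert np.allclose(diffs[np.arange(49) != 9], 0, atol=1e-9)

    def test_noiseless_spot_intensity_weakly_decreasing(self):
        cfg = SimConfig(seed=8, n_subunits=4, p_fluor=1.0, n_spots=3, noise_sd=0.0,
                        n_frames=60, image_shape=(64, 64))
        truth, _ = simulate_spot_population(cfg)
        movie = render_movie(truth, cfg)
        above_bg = (movie.data - cfg.background_level).sum(axis=(1, 2))
        assert np.all(np.diff(above_bg) <= 1e-9)


class TestFretGenerator:
    def test_zero_transfer_zero_scanloss_pre_equals_post(self):
        s = simulate_fret_pair(FretTruth(E_true=0.0, scan_loss_true=0.0))
        np.testing.assert_allclose(s.donor_pre, s.donor_post)

    def test_invalid_efficiency_rejected(self):
        with pytest.raises(ValueError, match="E_true"):
            FretTruth(E_true=1.0)

    def test_acceptor_bleached_only_in_roi(self):
        s = simulate_fret_pair(FretTruth(E_true=0.2, bleach_depth_true=0.8))
        assert np.all(s.acceptor_post[s.bleach_roi] < s.acceptor_pre[s.bleach_roi])
        outside = ~s.bleach_roi
        np.testing.assert_allclose(s.acceptor_post[outside], s.acceptor_pre[outside])


class TestColocGenerator:
    def test_zero_regulator_er_fraction_equals_amplitude(self):
        truth = ColocTruth(regulator_level=0.0, decay_amplitude=0.9, decay_offset=0.0)
        (s,) = simulate_coloc_panel([truth])
        er = s.channels["marker"] > 0
        frac = s.channels["reporter"][er].sum() / s.channels["reporter"][s.cell_mask].sum()
        assert frac == pytest.approx(0.9, abs=1e-12)

    def test_er_fraction_matches_closed_form(self):
        # ratio 1 at reporter level 100 -> regulator level 100
        truth = ColocTruth(regulator_level=100.0, decay_amplitude=0.9, decay_rate=1.5,
                           decay_offset=0.0)
        (s,) = simulate_coloc_panel([truth], ColocPanelConfig(reporter_level=100.0))
        er = s.channels["marker"] > 0
        frac = s.channels["reporter"][er].sum() / s.channels["reporter"][s.cell_mask].sum()
        assert frac == pytest.approx(0.9 * np.exp(-1.5), abs=1e-9)  # ~0.2008

    def test_intensity_conserved_between_masks(self):
        truths = [ColocTruth(regulator_level=lv) for lv in (0.0, 50.0, 150.0)]
        panel = simulate_coloc_panel(truths, ColocPanelConfig(reporter_level=100.0))
        for s in panel:
            total = s.channels["reporter"][s.cell_mask].sum()
            er = s.channels["marker"] > 0
            mb = s.cell_mask & ~er
            assert s.channels["reporter"][er].sum() + s.channels["reporter"][mb].sum() == pytest.approx(total)

    def test_er_fraction_monotone_in_regulator(self):
        levels = np.linspace(0, 300, 10)
        panel = simulate_coloc_panel([ColocTruth(regulator_level=lv) for lv in levels])
        fracs = []
        for s in panel:
            er = s.channels["marker"] > 0
            fracs.append(s.channels["reporter"][er].sum() / s.channels["reporter"][s.cell_mask].sum())
        assert np.all(np.diff(fracs) <= 1e-12)

    def test_identical_truths_identical_images(self):
        t = ColocTruth(regulator_level=80.0)
        p1 = simulate_coloc_panel([t], ColocPanelConfig(seed=3, noise_sd=2.0))
        p2 = simulate_coloc_panel([t], ColocPanelConfig(seed=3, noise_sd=2.0))
        np.testing.assert_array_equal(p1[0].channels["reporter"], p2[0].channels["reporter"])


def test_resolvable_step_count_handles_coincidence_and_survival():
    cfg = SimConfig(seed=0, n_frames=100, frame_interval=0.1)
    from oligotrace.synthetic import SpotTruth

    # two bleaches in the same frame interval resolve to one step
    s = SpotTruth(spot_id=0, position=(10, 10), n_fluorescent=2, bleach_times=(1.01, 1.05))
    assert resolvable_step_count(s, cfg) == 1
    # a fluorophore outliving the movie contributes no step
    s2 = SpotTruth(spot_id=1, position=(20, 20), n_fluorescent=2, bleach_times=(1.0, 99.0))
    assert resolvable_step_count(s2, cfg) == 1
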