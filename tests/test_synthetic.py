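"""Scene, TEM-population and mosaic generators: determinism, conservation,
analytic expectations."""

import math

import numpy as np
import pandas as pd
import pytest

from mitodyn.clonal import pooled_division_rate
from mitodyn.synthetic import (MorphPopConfig, MosaicConfig, OpticsConfig,
                               SceneConfig, ScheduleError, ScheduledEvent,
                               generate_scene, generate_tem_population,
                               render_frame, simulate_mosaic)


class TestGenerateScene:
    def test_no_events_conserves_count(self):
        truth = generate_scene(SceneConfig(n_objects=10, n_frames=10, seed=1))
        assert list(truth.counts()) == [10] * 10

    def test_scheduled_events_change_final_count(self):
        events = (
            ScheduledEvent(2, "fission", (0,)),
            ScheduledEvent(4, "fission", (1,)),
            ScheduledEvent(6, "fission", (2,)),
            ScheduledEvent(7, "fusion", (40, 41)),
        )
        truth = generate_scene(SceneConfig(n_objects=50, n_frames=10, seed=2,
                                           events=events))
        assert truth.counts()[-1] == 50 + 3 - 1

    def test_seeded_determinism(self):
        cfg = SceneConfig(n_objects=20, n_frames=8, seed=11,
                          fission_prob=0.05, fusion_prob=0.05)
        a, b = generate_scene(cfg), generate_scene(cfg)
        pd.testing.assert_frame_equal(a.objects_table(), b.objects_table())
        pd.testing.assert_frame_equal(a.events_table(), b.events_table())

    def test_fission_conserves_volume(self):
        truth = generate_scene(SceneConfig(
            n_objects=5, n_frames=4, seed=3,
            events=(ScheduledEvent(2, "fission", (0,)),),
        ))
        parent = next(o for o in truth.frames[1] if o.id == 0)
        children = [o for o in truth.frames[2] if o.id >= 5]
        assert len(children) == 2
        assert sum(c.volume for c in children) == pytest.approx(parent.volume, rel=1e-9)

    def test_fission_of_dead_object_rejected(self):
        events = (
            ScheduledEvent(2, "fusion", (0, 1)),
            ScheduledEvent(3, "fission", (0,)),  # 0 was consumed by the fusion
        )
        with pytest.raises(ScheduleError, match="not alive"):
            generate_scene(SceneConfig(n_objects=5, n_frames=5, seed=4, events=events))

    def test_fusion_without_enough_objects_rejected(self):
        with pytest.raises(ScheduleError):
            generate_scene(SceneConfig(
                n_objects=1, n_frames=3, seed=5,
                events=(ScheduledEvent(1, "fusion", (0, 1)),),
            ))

    @pytest.mark.parametrize("seed", range(5))
    def test_count_conservation_under_stochastic_program(self, seed):
        """N(t+1) = N(t) + fissions − fusions, frame by frame, vs the log."""
        truth = generate_scene(SceneConfig(
            n_objects=40, n_frames=12, seed=seed,
            fission_prob=0.05, fusion_prob=0.05,
        ))
        counts = truth.counts()
        for t in range(1, truth.n_frames):
            ev = truth.events[truth.events["transition"] == t]
            delta = sum(
                len(r["children"]) - 1 if r["kind"] == "fission"
                else -(len(r["parents"]) - 1)
                for _, r in ev.iterrows()
            )
            assert counts[t] == counts[t - 1] + delta

    def test_objects_stay_inside_grid(self):
        cfg = SceneConfig(n_objects=30, n_frames=15, seed=6, displacement_um=0.3)
        truth = generate_scene(cfg)
        extent = cfg.extent_um
        for frame in truth.frames:
            for o in frame:
                for d in range(3):
                    assert o.center[d] - o.semiaxes[d] >= 0
                    assert o.center[d] + o.semiaxes[d] <= extent[d]


class TestRenderFrame:
    def test_empty_frame_is_pure_background(self):
        truth = generate_scene(SceneConfig(n_objects=1, n_frames=2, seed=1))
        truth.frames[0] = []  # excise the object
        img = render_frame(truth, 1, OpticsConfig(background=7.0))
        assert np.all(img.data == 7.0)

    def test_bleaching_follows_exponential_decay(self):
        truth = generate_scene(SceneConfig(n_objects=5, n_frames=6, seed=2,
                                           displacement_um=0.0))
        b = 0.23
        optics = OpticsConfig(background=0.0, foreground=100.0, bleach_rate=b)
        f1 = render_frame(truth, 1, optics)
        fg1 = f1.data[f1.data > 0].mean()
        for k in (3, 6):
            fk = render_frame(truth, k, optics)
            fgk = fk.data[fk.data > 0].mean()
            assert fgk / fg1 == pytest.approx(math.exp(-b * (k - 1)), rel=1e-9)

    def test_rasterized_volume_matches_analytic_ellipsoid(self):
        cfg = SceneConfig(n_objects=1, n_frames=2, seed=3, semiaxes_cv=0.0)
        truth = generate_scene(cfg)
        o = truth.frames[0][0]
        img = render_frame(truth, 1, OpticsConfig(background=0.0, foreground=1.0))
        measured = (img.data > 0).sum() * img.voxel_volume
        analytic = 4 / 3 * math.pi * np.prod(o.semiaxes)
        # one-voxel-shell tolerance: volume difference of semi-axes ± h
        h = max(cfg.voxel_size)
        shell = 4 / 3 * math.pi * (
            np.prod([s + h for s in o.semiaxes]) - np.prod([max(s - h, 0) for s in o.semiaxes])
        )
        assert abs(measured - analytic) <= shell

    def test_subvoxel_object_warns(self):
        cfg = SceneConfig(n_objects=2, n_frames=2, seed=4)
        truth = generate_scene(cfg)
        o = truth.frames[0][0]
        truth.frames[0][0] = type(o)(o.id, o.center, (0.01, 0.01, 0.01))
        with pytest.warns(UserWarning, match="smaller than one voxel"):
            render_frame(truth, 1)

    def test_rendering_is_deterministic(self):
        truth = generate_scene(SceneConfig(n_objects=10, n_frames=3, seed=5))
        optics = OpticsConfig(shot_noise=True)
        a = render_frame(truth, 2, optics)
        b = render_frame(truth, 2, optics)
        np.testing.assert_array_equal(a.data, b.data)


class TestTemPopulation:
    def test_zero_dispersion_degenerates_to_means(self):
        pop = generate_tem_population(MorphPopConfig(n=50, area_sd=0.0, ratio_sd=0.0))
        assert np.all(pop["area_um2"] == 0.11)
        assert np.all(pop["ratio"] == 2.34)

    def test_sample_means_match_configured_means(self):
        pop = generate_tem_population(MorphPopConfig(n=10_000, seed=3))
        assert pop["area_um2"].mean() == pytest.approx(0.11, rel=0.02)
        assert pop["ratio"].mean() == pytest.approx(2.34, rel=0.02)

    def test_ratios_never_below_one(self):
        pop = generate_tem_population(MorphPopConfig(n=5000, seed=4))
        assert (pop["ratio"] >= 1).all()

    def test_seeded_determinism(self):
        cfg = MorphPopConfig(n=100, seed=9)
        pd.testing.assert_frame_equal(generate_tem_population(cfg),
                                      generate_tem_population(cfg))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            MorphPopConfig(area_mean=-0.1)
        with pytest.raises(ValueError):
            MorphPopConfig(ratio_mean=0.5)


class TestSimulateMosaic:
    def test_zero_hazard_keeps_every_gsc(self):
        df = simulate_mosaic(MosaicConfig(
            n_germaria=200, loss_hazard_neg=0.0, loss_hazard_pos=0.0, seed=1))
        assert (df["gsc_neg"] == 2).all() and (df["gsc_pos"] == 2).all()

    def test_survival_matches_closed_form(self):
        h, weeks, n = 0.2, 3, 1000
        df = simulate_mosaic(MosaicConfig(
            n_germaria=n, gsc_neg=1, gsc_pos=1, weeks=weeks,
            loss_hazard_neg=h, loss_hazard_pos=0.0, seed=2))
        for w in range(1, weeks + 1):
            frac = (df[df["week"] == w]["gsc_neg"] >= 1).mean()
            expected = (1 - h) ** w
            # 4-sigma binomial band
            tol = 4 * math.sqrt(expected * (1 - expected) / n)
            assert abs(frac - expected) <= tol

    def test_symmetric_lineages_give_unit_division_rate(self):
        df = simulate_mosaic(MosaicConfig(seed=0))
        result = pooled_division_rate(df, week=1)
        assert abs(result["rate"] - 1.0) < 0.05

    def test_estimator_deviation_shrinks_with_sample_size(self):
        """Mean |deviation from 1.0| across seeds shrinks roughly as 1/sqrt(n)."""
        def mean_abs_dev(n):
            devs = [
                abs(pooled_division_rate(
                    simulate_mosaic(MosaicConfig(n_germaria=n, loss_hazard_neg=0.0,
                                                 loss_hazard_pos=0.0, weeks=1,
                                                 seed=100 + s)),
                    week=1)["rate"] - 1.0)
                for s in range(6)
            ]
            return np.mean(devs)

        d50, d5000 = mean_abs_dev(50), mean_abs_dev(5000)
        assert d5000 < d50  # monotone shrinkage over a 100x size span

    def test_seeded_determinism(self):
        cfg = MosaicConfig(n_germaria=50, seed=13)
        pd.testing.assert_frame_equal(simulate_mosaic(cfg), simulate_mosaic(cfg))
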