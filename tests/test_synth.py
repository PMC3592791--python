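"""Synthetic plate generator: latent sampling, traces and rendered images."""

import numpy as np
import pandas as pd
import pytest

from quenchfit import synth
from quenchfit.synth import ConfigurationError, GroundTruthCell

from conftest import make_well


def _cell(**kwargs):
    defaults = dict(cell_id="c0", well_id="A1", class_label="pop", baseline_F=1000.0,
                    true_EC50=10.0, true_slope=1.0, true_dF=40.0, responder=True,
                    radius=6.0)
    defaults.update(kwargs)
    return GroundTruthCell(**defaults)


class TestSamplePopulation:
    def test_zero_spread_degenerate(self):
        spec = synth.PopulationSpec(name="a1", ec50_median=10.1, ec50_log_sd=0.0,
                                    slope_range=(1.2, 1.2), n_cells=5)
        cells = synth.sample_population(spec, seed=0)
        assert len(cells) == 5
        assert all(c.true_EC50 == pytest.approx(10.1) for c in cells)
        assert all(c.true_slope == pytest.approx(1.2) for c in cells)

    def test_sample_median_near_population_median(self):
        spec = synth.PopulationSpec(name="a2", ec50_median=49.0, ec50_log_sd=0.15,
                                    n_cells=1000)
        cells = synth.sample_population(spec, seed=1)
        med = np.median([c.true_EC50 for c in cells])
        assert abs(med - 49.0) / 49.0 < 0.10

    def test_no_responders(self):
        spec = synth.PopulationSpec(name="x", ec50_median=10, fraction_responders=0.0,
                                    n_cells=50)
        cells = synth.sample_population(spec, seed=0)
        assert all(not c.responder and c.true_dF == 0.0 for c in cells)

    def test_responder_fraction_within_binomial_error(self):
        spec = synth.PopulationSpec(name="x", ec50_median=10, fraction_responders=0.6,
                                    n_cells=400)
        cells = synth.sample_population(spec, seed=5)
        frac = np.mean([c.responder for c in cells])
        assert abs(frac - 0.6) < 4 * np.sqrt(0.6 * 0.4 / 400)

    def test_reproducible_for_fixed_seed(self):
        spec = synth.PopulationSpec(name="x", ec50_median=10, n_cells=20)
        a = synth.sample_population(spec, seed=9)
        b = synth.sample_population(spec, seed=9)
        assert [c.true_EC50 for c in a] == [c.true_EC50 for c in b]

    @pytest.mark.parametrize(
        "bad",
        [dict(ec50_median=-1.0), dict(fraction_responders=1.5),
         dict(dF_range=(20, 120)), dict(slope_range=(0.0, 1.0)), dict(n_cells=-1)],
    )
    def test_invalid_spec_names_field(self, bad):
        kwargs = {"name": "x", "ec50_median": 10, "n_cells": 5, **bad}
        spec = synth.PopulationSpec(**kwargs)
        with pytest.raises(ConfigurationError, match=next(iter(bad))):
            synth.sample_population(spec, seed=0)


class TestTrueResponse:
    def test_asymptote(self):
        cell = _cell(true_dF=40.0)
        assert synth.true_response(cell, 1e12) == pytest.approx(600.0, abs=1e-6)

    def test_midpoint_at_ec50(self):
        cell = _cell()
        assert synth.true_response(cell, 10.0) == pytest.approx(800.0)

    def test_non_responder_flat(self):
        cell = _cell(responder=False, true_dF=0.0)
        assert np.all(synth.true_response(cell, np.array([0.0, 1.0, 1e4])) == 1000.0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            synth.true_response(_cell(), -1.0)


class TestGenerateTraces:
    def test_noise_free_traces_equal_true_response(self, clean_well, ladder):
        traces, truth = synth.generate_traces(clean_well)
        from quenchfit.io import trace_concentrations

        conc, cols = trace_concentrations(traces)
        for (_, trow), (_, grow) in zip(traces.iterrows(), truth.iterrows()):
            cell = _cell(baseline_F=grow.baseline_F, true_EC50=grow.true_EC50,
                         true_slope=grow.true_slope, true_dF=grow.true_dF,
                         responder=grow.responder)
            np.testing.assert_allclose(trow[cols].to_numpy(dtype=float),
                                       synth.true_response(cell, conc), rtol=1e-12)

    def test_detachment_drops_to_background(self, alpha2_pop):
        well = make_well(alpha2_pop, detach_probability=1.0, seed=3)
        traces, truth = synth.generate_traces(well)
        from quenchfit.io import trace_concentrations

        _, cols = trace_concentrations(traces)
        bg = synth.BACKGROUND_FRAC * truth.baseline_F.mean()
        for (_, trow), (_, grow) in zip(traces.iterrows(), truth.iterrows()):
            k = int(grow.detach_frame)
            assert k >= 1
            tail = trow[cols].to_numpy(dtype=float)[k:]
            np.testing.assert_allclose(tail, bg, rtol=1e-9)

    def test_deterministic_per_seed(self, alpha2_pop):
        w = make_well(alpha2_pop, noise_sd_frac=0.02, debris_count=10,
                      detach_probability=0.1, seed=11)
        t1, g1 = synth.generate_traces(w)
        t2, g2 = synth.generate_traces(w)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(g1, g2)

    def test_mixture_separates_into_two_ec50_clusters(self):
        """Drug case study: homomer blocked (190 uM) vs heteromer spared (32 uM)."""
        a2 = synth.PopulationSpec(name="a2", ec50_median=190.0, n_cells=100)
        a2b = synth.PopulationSpec(name="a2b", ec50_median=32.0, n_cells=100)
        well = synth.WellSpec(well_id="A1", populations=[(a2, 0.5), (a2b, 0.5)],
                              n_cells=200, noise_sd_frac=0.0, seed=2)
        _, truth = synth.generate_traces(well)
        med_a2 = truth[truth.class_label == "a2"].true_EC50.median()
        med_a2b = truth[truth.class_label == "a2b"].true_EC50.median()
        assert med_a2 > 3 * med_a2b

    def test_mixing_fractions_must_sum_to_one(self, alpha2_pop):
        well = synth.WellSpec(well_id="A1", populations=[(alpha2_pop, 0.6)], seed=0)
        with pytest.raises(ConfigurationError, match="fractions"):
            synth.generate_traces(well)


class TestRenderImageSeries:
    def test_empty_well_is_background_only(self, alpha2_pop):
        well = make_well(synth.PopulationSpec(name="x", ec50_median=10, n_cells=0),
                         seed=1)
        series, truth = synth.render_image_series(well)
        assert len(truth) == 0
        assert series.frames.shape == (11, 520, 696)
        assert np.unique(series.frames).size == 1  # flat background, noise off

    def test_single_responder_disc_mean_tracks_true_response(self, ladder):
        pop = synth.PopulationSpec(name="a1", ec50_median=10.0, ec50_log_sd=0.0,
                                   fraction_responders=1.0, n_cells=1)
        well = make_well(pop, seed=4)
        series, truth = synth.render_image_series(well)
        row = truth.iloc[0]
        yy, xx = synth._disc_mask(series.frames[0].shape, row.x, row.y, row.radius)
        cell = _cell(baseline_F=row.baseline_F, true_EC50=row.true_EC50,
                     true_slope=row.true_slope, true_dF=row.true_dF)
        expected = synth.true_response(cell, ladder)
        measured = series.frames[:, yy, xx].mean(axis=1)
        np.testing.assert_allclose(measured, expected, atol=0.5)  # uint16 rounding

    def test_placement_of_300_cells_succeeds(self):
        pop = synth.PopulationSpec(name="a1", ec50_median=10.0, n_cells=300)
        well = make_well(pop, debris_count=100, seed=8)
        series, truth = synth.render_image_series(well)
        cells = truth[truth.class_label != "debris"]
        assert len(cells) == 300
        # pairwise non-overlap
        xy = cells[["x", "y"]].to_numpy()
        r = cells.radius.to_numpy()
        d = np.hypot(*(xy[:, None, :] - xy[None, :, :]).transpose(2, 0, 1))
        sep = d - (r[:, None] + r[None, :])
        np.testing.assert_array_less(0, sep + np.eye(len(r)) * 1e9)

    def test_trace_and_image_routes_agree_noise_free(self, alpha2_pop, ladder):
        well = make_well(alpha2_pop, seed=6)
        traces, truth_t = synth.generate_traces(well)
        series, truth_i = synth.render_image_series(well)
        # same latent cells on both routes
        pd.testing.assert_frame_equal(
            truth_t.drop(columns=["x", "y"]), truth_i.drop(columns=["x", "y"])
        )
        from quenchfit.io import trace_concentrations

        _, cols = trace_concentrations(traces)
        for (_, trow), (_, grow) in zip(traces.iterrows(), truth_i.iterrows()):
            yy, xx = synth._disc_mask(series.frames[0].shape, grow.x, grow.y, grow.radius)
            measured = series.frames[:, yy, xx].mean(axis=1)
            np.testing.assert_allclose(measured, trow[cols].to_numpy(dtype=float),
                                       atol=0.5)

    def test_render_deterministic_per_seed(self, alpha2_pop):
        well = make_well(alpha2_pop, noise_sd_frac=0.05, debris_count=20, seed=13)
        s1, g1 = synth.render_image_series(well)
        s2, g2 = synth.render_image_series(well)
        np.testing.assert_array_equal(s1.frames, s2.frames)
        pd.testing.assert_frame_equal(g1, g2)
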