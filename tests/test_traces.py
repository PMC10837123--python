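"""Import-trace normalisation, amplitude estimation, TMRM correction."""

import numpy as np
import pandas as pd
import pytest

import mitoquant as mq


def _trace(amplitude, rate=0.02, duration=1800.0, dt=6.0, noise_sd=0.0,
           seed=0, **kw):
    df = mq.gen_import_traces(amplitude, rate=rate, duration_s=duration,
                              dt=dt, noise_sd=noise_sd, seed=seed,
                              n_technical=1, **kw)
    return df["time_s"].to_numpy(), df["luminescence"].to_numpy()


class TestAmplitude:
    def test_noiseless_saturating_trace(self):
        t, y = _trace(50.0)
        res = mq.amplitude(t, y)
        assert res.amplitude == pytest.approx(50.0, abs=0.01)
        assert res.baseline == pytest.approx(0.0)

    def test_flat_trace_zero_amplitude(self):
        t = np.arange(0, 600, 6.0)
        assert mq.amplitude(t, np.full_like(t, 12.0)).amplitude == 0.0

    def test_additive_offset_invariance(self):
        t, y = _trace(80.0)
        assert mq.amplitude(t, y + 1234.5).amplitude == pytest.approx(
            mq.amplitude(t, y).amplitude)

    def test_trace_shorter_than_baseline_rejected(self):
        t = np.arange(0, 24, 6.0)
        with pytest.raises(ValueError, match="baseline"):
            mq.amplitude(t, np.zeros_like(t))

    def test_monte_carlo_bias_under_2_percent(self):
        """Noisy 30-min traces (noise sd = 2 % of A): |bias| < 2 %."""
        a_true = 100.0
        est = [mq.amplitude(*_trace(a_true, noise_sd=2.0, seed=s)).amplitude
               for s in range(100)]
        assert abs(np.mean(est) - a_true) / a_true < 0.02


class TestNormalizeTraces:
    def test_identical_replicates_stage2_identity(self):
        """Averaging identical technical replicates changes nothing: a
        3-replicate run and its single-replicate version normalise to the
        same traces and amplitudes."""
        three = mq.gen_import_traces(40.0, noise_sd=0.0, n_technical=3)
        one = mq.gen_import_traces(40.0, noise_sd=0.0, n_technical=1)
        norm3, res3 = mq.normalize_traces(three, None)
        norm1, res1 = mq.normalize_traces(one, None)
        np.testing.assert_allclose(norm3["lum_norm"], norm1["lum_norm"],
                                   rtol=1e-12)
        assert res3[0].amplitude == pytest.approx(res1[0].amplitude)

    def test_control_is_100_percent_of_itself(self):
        run = mq.gen_import_run({"ctl": 100.0, "half": 50.0}, noise_sd=0.0)
        _, results = mq.normalize_traces(run, "ctl")
        ctl = next(r for r in results if r.condition == "ctl")
        assert ctl.percent_of_control == pytest.approx(100.0)

    def test_paper_pair_reduction_33_5(self):
        """True amplitudes (100, 66.5) → a 33.5 % import reduction."""
        run = mq.gen_import_run({"ctl": 100.0, "noco_trap": 66.5},
                                noise_sd=0.5, seed=2)
        _, results = mq.normalize_traces(run, "ctl")
        amps = {r.condition: r.amplitude for r in results}
        red = mq.percent_reduction(amps["noco_trap"], amps["ctl"])
        assert red == pytest.approx(33.5, abs=0.5)

    def test_eqfp670_normalisation_removes_well_scaling(self):
        a = mq.gen_import_traces(60.0, condition="A", fluor_value=0.4,
                                 noise_sd=0.0)
        b = mq.gen_import_traces(60.0, condition="B", fluor_value=2.5,
                                 noise_sd=0.0, well_prefix="B")
        _, results = mq.normalize_traces(pd.concat([a, b]), "A")
        amps = [r.amplitude for r in results]
        assert amps[0] == pytest.approx(amps[1], rel=1e-9)

    def test_missing_control_flags_and_keeps_stage3(self):
        run = mq.gen_import_run({"A": 100.0, "B": 50.0}, noise_sd=0.0)
        with pytest.warns(UserWarning, match="absent"):
            _, results = mq.normalize_traces(run, "ghost")
        assert all(np.isnan(r.percent_of_control) for r in results)
        assert max(r.normalized_amplitude for r in results) == \
            pytest.approx(1.0)

    def test_stage_order_is_pinned(self):
        """Dividing by the control before run-max normalisation (swapped
        stages 3/4) yields a different percent-of-control whenever the
        control is not the run maximum — the pinned order reports the
        paper's ratio."""
        run = mq.gen_import_run({"big": 100.0, "ctl": 50.0}, noise_sd=0.0,
                                seed=4)
        _, results = mq.normalize_traces(run, "ctl")
        by = {r.condition: r for r in results}
        # pinned order: percent_of_control is the raw amplitude ratio
        assert by["big"].percent_of_control == pytest.approx(200.0, abs=0.2)
        # swapped order: stage 4 first, then divide by the max of the
        # control-normalised amplitudes
        ratios = {c: by[c].amplitude / by["ctl"].amplitude for c in by}
        swapped = {c: 100.0 * ratios[c] / max(ratios.values())
                   for c in ratios}
        assert swapped["big"] != pytest.approx(
            by["big"].percent_of_control, abs=1.0)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            mq.normalize_traces(pd.DataFrame({"time_s": [0.0]}), None)


class TestPercentReduction:
    @pytest.mark.parametrize("amp,ref,expect", [
        (100.0, 100.0, 0.0),
        (51.9, 100.0, 48.1),
        (63.2, 100.0, 36.8),
        (66.5, 100.0, 33.5),
    ])
    def test_values(self, amp, ref, expect):
        assert mq.percent_reduction(amp, ref) == pytest.approx(expect)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            mq.percent_reduction(10.0, 0.0)


class TestTmrmIntensity:
    def test_clean_collapse_recovers_pre_intensity(self):
        series, _ = mq.gen_tmrm_series(mito_intensity=100.0,
                                       post_cccp_intensity=0.0,
                                       noise_sd=0.0, seed=1)
        assert mq.tmrm_intensity(series) == pytest.approx(100.0)

    def test_no_collapse_gives_zero(self):
        series, _ = mq.gen_tmrm_series(mito_intensity=80.0,
                                       post_cccp_intensity=80.0,
                                       noise_sd=0.0, seed=1)
        assert mq.tmrm_intensity(series) == pytest.approx(0.0)

    def test_noised_series_matches_pixel_arithmetic(self):
        """Corrected intensity equals a direct-loop recomputation."""
        series, _ = mq.gen_tmrm_series(mito_intensity=100.0,
                                       post_cccp_intensity=10.0,
                                       noise_sd=3.0, seed=7)
        movie = series.pixels
        pre = sum(movie[f] for f in range(10)) / 10.0
        post = sum(movie[-(f + 1)] for f in range(3)) / 3.0
        mask = mq.binarize(pre, "otsu")
        manual = float(np.mean((pre - post)[mask]))
        assert mq.tmrm_intensity(series) == pytest.approx(manual)

    def test_short_series_rejected(self):
        series, _ = mq.gen_tmrm_series(n_frames=8, cccp_frame=5)
        with pytest.raises(ValueError, match="frames"):
            mq.tmrm_intensity(series, n_first=10, n_last=3)
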