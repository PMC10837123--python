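"""Generators: determinism, ground-truth bookkeeping, closed-form signals."""

import numpy as np
import pytest

import mitoquant as mq


class TestMitoImage:
    def test_single_straight_tube_gives_one_object(self):
        params = mq.PhantomParams(image_shape=(128, 128), n_tubes=1,
                                  curvature=0.0, psf_sigma=0.0,
                                  gaussian_sd=0.0, seed=7)
        _, truth = mq.gen_mito_image(params)
        assert truth.n_objects == 1
        from scipy import ndimage as ndi
        _, n = ndi.label(truth.label_map > 0, structure=np.ones((3, 3)))
        assert n == 1

    def test_object_count_matches_overlap_accounting(self):
        """Connected components = n_tubes − merges enumerated from the
        ground-truth overlap record (union-find over colliding pairs)."""
        params = mq.PhantomParams(image_shape=(512, 512), n_tubes=50,
                                  tube_length_range=(30.0, 60.0),
                                  psf_sigma=0.0, gaussian_sd=0.0, seed=11)
        _, truth = mq.gen_mito_image(params)
        parent = list(range(params.n_tubes + 1))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for a, b in truth.overlap_pairs:
            parent[find(a)] = find(b)
        groups = {find(lab) for lab in truth.labels}
        from scipy import ndimage as ndi
        _, n_cc = ndi.label(truth.label_map > 0, structure=np.ones((3, 3)))
        assert n_cc == len(groups)

    def test_too_small_image_fails(self):
        with pytest.raises(ValueError, match="too small"):
            mq.gen_mito_image(mq.PhantomParams(image_shape=(8, 8)))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            mq.PhantomParams(tube_radius=0.5)
        with pytest.raises(ValueError):
            mq.PhantomParams(branch_prob=1.5)


class TestAssociationChannel:
    @pytest.fixture
    def truth(self):
        params = mq.PhantomParams(image_shape=(256, 256), n_tubes=12,
                                  psf_sigma=0.0, gaussian_sd=0.0, seed=3)
        return mq.gen_mito_image(params)[1]

    def test_fraction_zero_is_background_only(self, truth):
        ch = mq.gen_association_channel(truth, 0.0, gaussian_sd=0.0, seed=1)
        assert np.all(ch == 0)
        assert truth.associated_labels == set()

    def test_fraction_one_shells_every_object(self, truth):
        mq.gen_association_channel(truth, 1.0, seed=1)
        assert truth.associated_labels == truth.labels
        assert truth.true_association_fraction == 1.0

    def test_round_half_away_from_zero(self):
        # 0.433 × 200 = 86.6 → 87 shelled objects
        assert mq.round_half_away(0.433 * 200) == 87
        assert mq.round_half_away(0.5) == 1
        assert mq.round_half_away(-0.5) == -1
        assert mq.round_half_away(2.49) == 2

    def test_paper_fraction_bookkeeping_n200(self):
        params = mq.PhantomParams(image_shape=(1024, 1024), n_tubes=200,
                                  tube_length_range=(15.0, 30.0), seed=5)
        _, truth = mq.gen_mito_image(params)
        assert truth.n_objects == 200
        mq.gen_association_channel(truth, 0.433, seed=6)
        assert len(truth.associated_labels) == 87
        assert truth.true_association_fraction == 87 / 200

    def test_negative_shell_intensity_fails(self, truth):
        with pytest.raises(ValueError):
            mq.gen_association_channel(truth, 0.5, shell_intensity=-1)

    def test_shell_sits_in_exterior_band(self, truth):
        from scipy import ndimage as ndi
        ch = mq.gen_association_channel(truth, 1.0, shell_width=4.0,
                                        psf_sigma=0.0, gaussian_sd=0.0,
                                        seed=2)
        dist = ndi.distance_transform_edt(truth.label_map == 0)
        assert np.all(ch[(dist == 0) | (dist > 4.0)] == 0)
        assert ch[(dist > 0) & (dist <= 4.0)].max() > 0


class TestMixingImage:
    def test_disjoint_supports_at_zero(self):
        params = mq.PhantomParams(image_shape=(256, 256), n_tubes=20,
                                  psf_sigma=0.0, gaussian_sd=0.0)
        stack, truth = mq.gen_mixing_image(0.0, params, seed=4)
        g, r = stack.channel(0), stack.channel(1)
        assert not np.any((g > 0) & (r > 0))
        assert truth.dual_labels == set()
        assert truth.true_mixing_pcc_regime == "unmixed"

    def test_full_mixing_duplicates_channels(self):
        params = mq.PhantomParams(image_shape=(256, 256), n_tubes=20,
                                  psf_sigma=0.0, gaussian_sd=0.0)
        stack, truth = mq.gen_mixing_image(1.0, params, seed=4)
        assert truth.dual_labels == truth.labels
        np.testing.assert_array_equal(stack.channel(0), stack.channel(1))

    def test_half_mixing_counts(self):
        params = mq.PhantomParams(image_shape=(1024, 1024), n_tubes=100,
                                  tube_length_range=(15.0, 30.0))
        _, truth = mq.gen_mixing_image(0.5, params, seed=4)
        assert len(truth.dual_labels) == 50


class TestImportTraces:
    def test_noiseless_trace_saturates_at_amplitude(self):
        df = mq.gen_import_traces(amplitude=50.0, rate=0.02,
                                  duration_s=3600.0, noise_sd=0.0)
        final = df[df["time_s"] == df["time_s"].max()]["luminescence"]
        assert final.iloc[0] == pytest.approx(50.0, rel=1e-6)

    def test_zero_amplitude_is_flat(self):
        df = mq.gen_import_traces(amplitude=0.0, noise_sd=0.0)
        assert np.all(df["luminescence"] == 0)

    def test_baseline_is_silent_for_30s(self):
        df = mq.gen_import_traces(amplitude=100.0, noise_sd=0.0)
        assert np.all(df.loc[df["time_s"] <= 30.0, "luminescence"] == 0)

    def test_run_encodes_percent_reduction(self):
        """Amplitudes (100, 51.9) encode the 48.1% import reduction."""
        run = mq.gen_import_run({"ctl": 100.0, "trap": 51.9}, noise_sd=0.0,
                                seed=9)
        _, results = mq.normalize_traces(run, "ctl")
        amps = {r.condition: r.amplitude for r in results}
        assert mq.percent_reduction(amps["trap"], amps["ctl"]) == \
            pytest.approx(48.1, abs=0.05)


class TestTmrmSeries:
    def test_axes_and_collapse(self):
        stack, truth = mq.gen_tmrm_series(mito_intensity=80.0,
                                          post_cccp_intensity=10.0,
                                          cccp_frame=14, seed=2)
        assert stack.axes == "TYX"
        obj = truth.label_map > 0
        assert np.all(stack.pixels[0][obj] == 80.0)
        assert np.all(stack.pixels[-1][obj] == 10.0)


class TestProteinTable:
    def test_planted_shift_on_log2_scale(self):
        table, truth = mq.gen_protein_table(200, 20, log2_effect=5.0,
                                            replicate_sd=0.0, seed=8)
        logged = np.log2(table)
        plus = logged.filter(like="plus").mean(axis=1)
        minus = logged.filter(like="minus").mean(axis=1)
        shift = (plus - minus)
        planted = shift.loc[sorted(truth.true_enriched_ids)]
        others = shift.drop(index=sorted(truth.true_enriched_ids))
        assert np.allclose(planted, 5.0)
        assert np.allclose(others, 0.0)


@pytest.mark.parametrize("make", [
    lambda s: mq.gen_mito_image(mq.PhantomParams(
        image_shape=(128, 128), n_tubes=6, seed=s))[0].pixels,
    lambda s: mq.gen_mixing_image(0.5, mq.PhantomParams(
        image_shape=(128, 128), n_tubes=6), seed=s)[0].pixels,
    lambda s: mq.gen_import_traces(100.0, noise_sd=2.0, seed=s)
    ["luminescence"].to_numpy(),
    lambda s: mq.gen_tmrm_series(noise_sd=2.0, seed=s)[0].pixels,
    lambda s: mq.gen_protein_table(50, 5, seed=s)[0].to_numpy(),
], ids=["mito_image", "mixing", "traces", "tmrm", "proteins"])
def test_generators_bit_reproducible(make):
    """Same seed ⇒ bit-identical output; different seed ⇒ different."""
    a, b = make(42), make(42)
    np.testing.assert_array_equal(a, b)
    assert not np.array_equal(a, make(43))
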