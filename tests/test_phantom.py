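"""Phantom generation, signal simulation and reformatting."""

import numpy as np
import pytest

from dixonfgt import (
    SequenceParams,
    TissueProperties,
    generate_phantom,
    get_preset,
    reformat,
    simulate_dixon_acquisition,
    true_fgt_percent,
)
from dixonfgt.image import VolumeImage
from dixonfgt.phantom import (
    LABEL_BREAST_L,
    LABEL_BREAST_R,
    BreastGeometry,
    polynomial_bias,
)

from conftest import make_spec


class TestGeneratePhantom:
    @pytest.mark.parametrize("fraction,expected", [(0.0, 0.0), (1.0, 100.0), (0.5, 50.0)])
    def test_uniform_composition_gives_exact_truth(self, fraction, expected):
        ph = generate_phantom(make_spec({"kind": "uniform", "fraction": fraction}))
        assert true_fgt_percent(ph, "R") == pytest.approx(expected, abs=1e-12)
        assert true_fgt_percent(ph, "L") == pytest.approx(expected, abs=1e-12)

    def test_constant_field_truth(self):
        ph = generate_phantom(make_spec({"kind": "uniform", "fraction": 0.364}))
        assert true_fgt_percent(ph, "R") == pytest.approx(36.4, abs=1e-9)

    def test_truth_matches_brute_force_sum(self):
        """%FGT equals an explicit per-voxel summation over the label list."""
        rng = np.random.default_rng(4)
        spec = make_spec(seed=4)
        field = rng.uniform(0, 1, size=spec.grid_shape)
        ph = generate_phantom(make_spec({"kind": "field", "values": field}, seed=4))
        acc, n = 0.0, 0
        for idx in np.argwhere(ph.labels == LABEL_BREAST_R):
            acc += ph.v[tuple(idx)]
            n += 1
        assert true_fgt_percent(ph, "R") == pytest.approx(100.0 * acc / n, rel=1e-12)

    def test_mirror_symmetric_breasts_agree(self):
        ph = generate_phantom(make_spec({"kind": "uniform", "fraction": 0.3}))
        nR = (ph.labels == LABEL_BREAST_R).sum()
        nL = (ph.labels == LABEL_BREAST_L).sum()
        assert nR == nL
        assert true_fgt_percent(ph, "R") == pytest.approx(true_fgt_percent(ph, "L"))

    def test_labels_partition_grid(self, blob_phantom):
        assert set(np.unique(blob_phantom.labels)) <= {0, 1, 2, 3}
        outside = blob_phantom.labels == 0
        assert np.all(blob_phantom.v[outside] == 0)
        assert blob_phantom.v.min() >= 0 and blob_phantom.v.max() <= 1

    def test_oversized_breast_names_side(self):
        spec = make_spec()
        bad = BreastGeometry(spec.breasts[0].center_mm, (500.0, 30.0, 20.0))
        spec2 = make_spec()
        spec2.breasts = (bad, spec.breasts[1])
        with pytest.raises(ValueError, match="right"):
            generate_phantom(spec2)

    def test_seeded_determinism(self):
        a = generate_phantom(make_spec(seed=9))
        b = generate_phantom(make_spec(seed=9))
        assert np.array_equal(a.v, b.v)
        assert np.array_equal(a.labels, b.labels)

    def test_empty_side_errors(self, blob_phantom):
        with pytest.raises(ValueError):
            true_fgt_percent(blob_phantom, "X")


class TestSignalModel:
    def test_spgr_limit_recovers_proton_density(self):
        """At 90 degrees, TR >> T1 and TE -> 0 the SPGR signal tends to PD."""
        seq = SequenceParams(family="GRE_SPGR", TR_ms=1e9, TE_in_ms=1e-6,
                             TE_out_ms=5e-7, flip_angle_deg=90.0)
        assert seq.species_signal(0.7, 1000.0, 80.0, "in") == pytest.approx(0.7, rel=1e-6)

    def test_preset_parameters(self):
        pd = get_preset("hr-gre-pd")
        assert (pd.TR_ms, pd.TE_in_ms, pd.TE_out_ms, pd.flip_angle_deg) == (
            7.34, 4.77, 2.39, 4.0)
        t1 = get_preset("hr-gre-t1")
        assert t1.flip_angle_deg == 25.0
        se = get_preset("lr-se-t1")
        assert se.family == "SE" and se.TR_ms == 500.0 and se.TE_in_ms == 12.0
        assert se.echo_train_length == 8 and se.echo_spacing_ms == 12.2

    def test_pure_water_echoes_have_equal_magnitude(self, single_peak_tissues):
        ph = generate_phantom(make_spec({"kind": "uniform", "fraction": 1.0}))
        ep = simulate_dixon_acquisition(ph, single_peak_tissues, "hr-gre-pd")
        breast = (ph.labels == LABEL_BREAST_R) | (ph.labels == LABEL_BREAST_L)
        np.testing.assert_allclose(
            np.abs(ep.in_phase.data[breast]),
            np.abs(ep.out_of_phase.data[breast]), rtol=1e-12,
        )

    def test_equal_species_cancel_at_exact_opposed_phase(self):
        """A 50/50 voxel with matched species signals nulls the opposed echo."""
        tissues = TissueProperties(
            water_T1_ms=800.0, fat_T1_ms=800.0, water_T2_ms=60.0, fat_T2_ms=60.0,
        ).single_peak()
        f0 = abs(tissues.fat_spectrum[0][0])
        seq = SequenceParams(family="GRE_SPGR", TR_ms=7.34,
                             TE_in_ms=1000.0 / f0, TE_out_ms=500.0 / f0,
                             flip_angle_deg=4.0)
        ph = generate_phantom(make_spec({"kind": "uniform", "fraction": 0.5}))
        ep = simulate_dixon_acquisition(ph, tissues, seq)
        breast = (ph.labels == LABEL_BREAST_R) | (ph.labels == LABEL_BREAST_L)
        assert np.abs(ep.out_of_phase.data[breast]).max() < 1e-12
        assert np.abs(ep.in_phase.data[breast]).min() > 0

    def test_seeded_noise_is_reproducible(self, blob_phantom, multi_peak_tissues):
        kw = dict(noise_sd=0.02, rng_seed=123)
        a = simulate_dixon_acquisition(blob_phantom, multi_peak_tissues, "hr-gre-pd", **kw)
        b = simulate_dixon_acquisition(blob_phantom, multi_peak_tissues, "hr-gre-pd", **kw)
        assert np.array_equal(a.in_phase.data, b.in_phase.data)
        assert np.array_equal(a.out_of_phase.data, b.out_of_phase.data)

    def test_multi_peak_fat_leaks_more_water_in_se(self, multi_peak_tissues):
        """With the six-peak spectrum, pure fat shows a higher apparent
        water fraction in the spin-echo preset than in the PD-weighted
        gradient-echo preset (the spectral model is coherent at the spin
        echo but partially dephased at the gradient-echo in-phase TE)."""
        from dixonfgt import two_point_separation

        ph = generate_phantom(make_spec({"kind": "uniform", "fraction": 0.0}))
        fat = (ph.labels == LABEL_BREAST_R) | (ph.labels == LABEL_BREAST_L)
        apparent = {}
        for preset in ("hr-gre-pd", "lr-se-t1"):
            ep = simulate_dixon_acquisition(ph, multi_peak_tissues, preset)
            pair = two_point_separation(ep)
            w = pair.water.data[fat]
            f = pair.fat.data[fat]
            apparent[preset] = float((w / (w + f)).mean())
        assert apparent["lr-se-t1"] > apparent["hr-gre-pd"]

    def test_bias_field_scales_signal(self, blob_phantom, single_peak_tissues):
        bias = polynomial_bias(blob_phantom.shape, {(1, 0, 0): 0.2, (0, 2, 0): -0.1})
        ep0 = simulate_dixon_acquisition(blob_phantom, single_peak_tissues, "hr-gre-pd")
        ep1 = simulate_dixon_acquisition(blob_phantom, single_peak_tissues, "hr-gre-pd",
                                         bias_field=bias)
        np.testing.assert_allclose(ep1.in_phase.data, ep0.in_phase.data * bias)

    def test_unknown_family_and_bad_noise_rejected(self, blob_phantom):
        with pytest.raises(ValueError):
            SequenceParams(family="bSSFP", TR_ms=5.0, TE_in_ms=2.0, TE_out_ms=1.0)
        with pytest.raises(ValueError):
            simulate_dixon_acquisition(blob_phantom, None, "hr-gre-pd", noise_sd=-0.1)


class TestReformat:
    def test_constant_volume_stays_constant(self):
        vol = VolumeImage(np.full((20, 20, 20), 3.7), (1.3, 1.3, 1.0))
        out = reformat(vol, (0.8, 0.8, 7.0))
        interior = out.data[1:-1, 1:-1, 1:-1]
        np.testing.assert_allclose(interior, 3.7, rtol=1e-12)

    def test_grid_dimensions_match_extent_arithmetic(self):
        vol = VolumeImage(np.zeros((96, 64, 48)), (1.3, 1.3, 1.0))
        out = reformat(vol, (0.8, 0.8, 7.0))
        expected = tuple(
            int(np.ceil(n * s / t))
            for n, s, t in zip((96, 64, 48), (1.3, 1.3, 1.0), (0.8, 0.8, 7.0))
        )
        assert out.shape == expected
        assert out.spacing == (0.8, 0.8, 7.0)

    def test_identity_spacing_is_identity(self):
        rng = np.random.default_rng(0)
        vol = VolumeImage(rng.uniform(size=(12, 13, 14)), (1.0, 1.1, 1.2))
        out = reformat(vol, vol.spacing)
        assert out.shape == vol.shape
        np.testing.assert_allclose(out.data, vol.data, atol=1e-12)

    def test_rejects_nonpositive_spacing(self):
        vol = VolumeImage(np.zeros((4, 4, 4)), (1, 1, 1))
        with pytest.raises(ValueError):
            reformat(vol, (0.0, 1.0, 1.0))
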