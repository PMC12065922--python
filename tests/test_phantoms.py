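import numpy as np
import pytest
from hypothesis import given, strategies as st

from paitwin.phantoms import (BVF_FLOOR, DISEASE_STATES, DiseaseState,
                              GeometryConfig, NodeGroundTruth,
                              PhantomGenerationError, TissueProperties,
                              build_phantom, clipped_normal_mean,
                              compute_absorption, default_property_table,
                              generate_label_map, sample_node_properties)


class TestDiseaseStates:
    def test_presets_match_clinical_values(self):
        m = DISEASE_STATES["malignant"]
        assert (m.bvf_mean, m.bvf_sd, m.so2_mean, m.so2_sd) == (
            0.04, 0.02, 0.43, 0.15)
        b = DISEASE_STATES["benign"]
        assert (b.bvf_mean, b.bvf_sd, b.so2_mean, b.so2_sd) == (
            0.14, 0.07, 0.73, 0.15)
        i = DISEASE_STATES["intermediate"]
        assert (i.bvf_mean, i.bvf_sd, i.so2_mean, i.so2_sd) == (
            0.09, 0.045, 0.58, 0.15)

    def test_invalid_state_rejected(self):
        with pytest.raises(ValueError):
            DiseaseState("bad", 1.5, 0.1, 0.5, 0.1)
        with pytest.raises(ValueError):
            sample_node_properties("necrotic", 0)

    @pytest.mark.parametrize("name", sorted(DISEASE_STATES))
    def test_sample_mean_matches_clipped_distribution(self, name):
        state = DISEASE_STATES[name]
        rng = np.random.default_rng(123)
        draws = [sample_node_properties(state, rng) for _ in range(10_000)]
        so2 = np.array([d.so2 for d in draws])
        bvf = np.array([d.bvf for d in draws])
        mu_so2 = clipped_normal_mean(state.so2_mean, state.so2_sd, 0.0, 1.0)
        mu_bvf = clipped_normal_mean(state.bvf_mean, state.bvf_sd,
                                     BVF_FLOOR, 1.0)
        assert abs(so2.mean() - mu_so2) < 3 * state.so2_sd / 100
        assert abs(bvf.mean() - mu_bvf) < 3 * state.bvf_sd / 100

    def test_clipping_bias_below_printed_tolerance(self):
        # brute-force check that clipping shifts the mean < 0.3 pp
        for state in DISEASE_STATES.values():
            rng = np.random.default_rng(7)
            raw_bvf = rng.normal(state.bvf_mean, state.bvf_sd, 200_000)
            bias = np.clip(raw_bvf, BVF_FLOOR, 1).mean() - state.bvf_mean
            assert abs(bias) < 0.003
            raw_so2 = rng.normal(state.so2_mean, state.so2_sd, 200_000)
            assert abs(np.clip(raw_so2, 0, 1).mean() - state.so2_mean) < 0.003

    def test_degenerate_state_returns_means(self):
        state = DiseaseState("fixed", 0.1, 0.0, 0.6, 0.0)
        gt = sample_node_properties(state, 5)
        assert (gt.bvf, gt.so2) == (0.1, 0.6)

    def test_draws_respect_bounds(self):
        state = DISEASE_STATES["malignant"]
        rng = np.random.default_rng(99)
        for _ in range(500):
            gt = sample_node_properties(state, rng)
            assert 0.0 <= gt.so2 <= 1.0
            assert gt.bvf >= BVF_FLOOR

    def test_seed_determinism(self):
        a = sample_node_properties("benign", 42)
        b = sample_node_properties("benign", 42)
        assert (a.bvf, a.so2) == (b.bvf, b.so2)


class TestLabelMaps:
    def test_default_map_satisfies_invariants(self, small_geometry):
        lm = generate_label_map(small_geometry, 0)
        lm.validate()
        assert lm.present_classes() >= {
            "coupling_medium", "membrane", "ultrasound_gel", "dermis",
            "subcutis", "bulk_tissue", "lymph_node"}

    def test_zero_radius_gives_no_node(self, small_geometry):
        geom = GeometryConfig(shape=small_geometry.shape,
                              spacing=small_geometry.spacing,
                              node_radius_range=(0.0, 0.0))
        lm = generate_label_map(geom, 0)
        assert not lm.mask("lymph_node").any()

    def test_seed_determinism(self, small_geometry):
        a = generate_label_map(small_geometry, 3)
        b = generate_label_map(small_geometry, 3)
        assert np.array_equal(a.labels, b.labels)

    def test_impossible_node_raises(self):
        geom = GeometryConfig(shape=(64, 32), spacing=0.1,
                              node_depth_range=(30.0, 30.0))
        with pytest.raises(PhantomGenerationError):
            generate_label_map(geom, 0)


class TestAbsorption:
    def test_pure_chromophore_identity(self, spectra):
        comp = TissueProperties(blood_volume_fraction=1.0, so2=1.0)
        assert compute_absorption(comp, spectra, 800) == pytest.approx(
            spectra.absorption("hbo2", 800))

    def test_empty_composition_is_transparent(self, spectra):
        comp = TissueProperties()
        assert compute_absorption(comp, spectra, 800) == 0.0
        assert compute_absorption(comp, spectra, 800, background=0.01) == 0.01

    @given(bvf=st.floats(0, 1), so2=st.floats(0, 1), w=st.floats(0, 1),
           f=st.floats(0, 1))
    def test_linearity_in_fractions(self, spectra, bvf, so2, w, f):
        lam = 760
        full = compute_absorption(
            TissueProperties(blood_volume_fraction=bvf, so2=so2,
                             water_fraction=w, fat_fraction=f), spectra, lam)
        blood = compute_absorption(
            TissueProperties(blood_volume_fraction=bvf, so2=so2),
            spectra, lam)
        rest = compute_absorption(
            TissueProperties(water_fraction=w, fat_fraction=f), spectra, lam)
        assert np.isclose(full, blood + rest, rtol=1e-12, atol=1e-14)

    def test_saturation_irrelevant_at_isosbestic_point(self, spectra):
        lam = spectra.isosbestic_wavelength()
        vals = [compute_absorption(
            TissueProperties(blood_volume_fraction=0.04, so2=s), spectra, lam)
            for s in np.linspace(0, 1, 11)]
        assert (max(vals) - min(vals)) / np.mean(vals) < 0.01

    def test_out_of_range_wavelength_raises(self, spectra):
        with pytest.raises(ValueError):
            compute_absorption(TissueProperties(water_fraction=1.0),
                               spectra, 1500)


class TestBuildPhantom:
    def test_uniform_map_gives_constant_grids(self, spectra):
        from paitwin.phantoms import LabelMap
        lm = LabelMap(labels=np.full((16, 8), 5, dtype=np.uint8), spacing=0.2)
        ph = build_phantom(lm, None, None, wavelengths=(800,),
                          bvf_heterogeneity=0.0)
        assert np.ptp(ph.mua[0]) == 0
        assert np.ptp(ph.mus_reduced[0]) == 0
        assert np.ptp(ph.sos) == 0

    def test_node_truth_assigned_exactly(self, node_phantom):
        node = node_phantom.node_mask()
        assert node_phantom.so2_truth[node].mean() == pytest.approx(0.58)
        # texture is mean-preserving over the node region
        assert node_phantom.bvf_truth[node].mean() == pytest.approx(0.09)

    def test_mua_positive_in_all_tissue(self, node_phantom):
        for cls in ("dermis", "subcutis", "bulk_tissue", "lymph_node"):
            mask = node_phantom.label_map.mask(cls)
            assert np.all(node_phantom.mua[:, mask] > 0)

    def test_scattering_power_law(self, spectra):
        from paitwin.phantoms import LabelMap
        lm = LabelMap(labels=np.full((4, 4), 5, dtype=np.uint8), spacing=0.2)
        ph = build_phantom(lm, None, None, wavelengths=(700, 1050))
        table = default_property_table()["bulk_tissue"]
        b = table.scattering_power
        assert ph.mus_reduced[0, 0, 0] == pytest.approx(
            table.mus500 * (700 / 500) ** (-b))
        assert ph.mus_reduced[1, 0, 0] / ph.mus_reduced[0, 0, 0] == \
            pytest.approx((1050 / 700) ** (-b))

    def test_end_to_end_seed_determinism(self, small_geometry):
        def build():
            truth = sample_node_properties("malignant", 21)
            lm = generate_label_map(small_geometry, 22)
            return build_phantom(lm, None, truth, wavelengths=(800,),
                                 texture_seed=23)
        a, b = build(), build()
        assert np.array_equal(a.mua, b.mua)
        assert np.array_equal(a.label_map.labels, b.label_map.labels)

    def test_missing_class_raises(self, small_geometry):
        lm = generate_label_map(small_geometry, 0)
        table = {k: v for k, v in default_property_table().items()
                 if k != "subcutis"}
        with pytest.raises(KeyError):
            build_phantom(lm, table, NodeGroundTruth(0.1, 0.5), (800,))

    def test_node_without_truth_raises(self, small_geometry):
        lm = generate_label_map(small_geometry, 0)
        with pytest.raises(ValueError):
            build_phantom(lm, None, None, (800,))
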