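"""Layered head phantom, tissue properties, impedances, forward model."""

import dataclasses

import numpy as np
import pytest
from shapely.geometry import LineString

import mwbrain as m
from mwbrain.constants import C0_MM, ETA0
from mwbrain.geometry import InvalidGeometryError
from mwbrain.phantom import (
    DEFAULT_TISSUES,
    ForwardConfig,
    insert_target,
    make_head_phantom,
    simulate_reflection,
    straight_ray_delay,
)


class TestTissueTable:
    @pytest.mark.parametrize("tissue,f,expect", [
        ("skin", 0.75e9, 50.0),
        ("skin", 2.55e9, 44.0),
        ("csf", 2.55e9, 66.2),
        ("dura", 0.75e9, 44.0),
        ("muscle", 0.75e9, 55.0),
    ])
    def test_band_edges(self, tissue, f, expect):
        assert m.tissue_permittivity(tissue, f) == expect

    def test_band_midpoint_is_mean(self):
        mid = (0.75e9 + 2.55e9) / 2
        for t, (lo, hi, _) in DEFAULT_TISSUES.items():
            assert m.tissue_permittivity(t, mid) == pytest.approx((lo + hi) / 2)

    def test_unknown_tissue_and_out_of_band(self):
        with pytest.raises(ValueError):
            m.tissue_permittivity("bone_marrow", 1e9)
        with pytest.raises(ValueError):
            m.tissue_permittivity("skin", 5e9)


class TestWaveImpedance:
    def test_vacuum_limit(self):
        assert m.wave_impedance(1.0, 0.0, 1e9) == pytest.approx(ETA0, rel=1e-6)

    def test_lossless_scaling(self):
        assert m.wave_impedance(4.0, 0.0, 1e9) == pytest.approx(ETA0 / 2, rel=1e-6)

    def test_lossy_case_against_direct_complex_oracle(self):
        from mwbrain.constants import EPS0, MU0

        for eps_r, sigma, f in [(50.0, 1.0, 0.75e9), (44.0, 1.8, 2.55e9)]:
            w = 2 * np.pi * f
            expect = abs(np.sqrt(1j * w * MU0 / (sigma + 1j * w * EPS0 * eps_r)))
            assert m.wave_impedance(eps_r, sigma, f) == pytest.approx(expect, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            m.wave_impedance(0.5, 0.0, 1e9)


class TestImpedanceContrast:
    def test_printed_band_edge_contrasts(self):
        # blood vs gray matter at the printed band-edge impedances
        assert round(m.impedance_contrast(44.8, 48.9), 1) == 9.2
        assert round(m.impedance_contrast(49.9, 52.5), 1) == 5.2

    def test_equal_impedances_zero(self):
        assert m.impedance_contrast(50.0, 50.0) == 0.0

    def test_gray_vs_white_background_ordering(self):
        # Fresnel contrast of blood against white matter exceeds that against
        # gray matter (ordering only; the magnitudes are model-specific)
        fc = 1.6e9
        eps_blood = m.tissue_permittivity("blood", fc)
        eps_gray = m.tissue_permittivity("gray", fc)
        eps_white = m.tissue_permittivity("white", fc)

        def fresnel(a, b):
            return abs((np.sqrt(a) - np.sqrt(b)) / (np.sqrt(a) + np.sqrt(b)))

        assert fresnel(eps_white, eps_blood) > fresnel(eps_gray, eps_blood)


class TestPhantomGeometry:
    def test_default_constructor_valid(self):
        ph = make_head_phantom(target=None)
        assert ph.boundary.n_vertices == 180
        assert ph.target is None

    def test_insert_target_and_replace(self):
        ph = make_head_phantom()
        ph1 = insert_target(ph, (20.0, 30.0), 20.0, 20.0)
        ph2 = insert_target(ph1, (0.0, 40.0), 20.0, 20.0)
        assert ph2.target.center == (0.0, 40.0)

    def test_target_straddling_boundary_rejected(self):
        ph = make_head_phantom()
        with pytest.raises(InvalidGeometryError):
            insert_target(ph, (85.0, 0.0), 20.0, 20.0)

    def test_tissue_partition_unique_over_grid(self):
        ph = insert_target(make_head_phantom(), (0.0, 40.0), 20.0, 20.0)
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(200):
            pt = rng.uniform([-88.0, -108.0], [88.0, 108.0])
            if ph.outer_polygon.covers(__import__("shapely.geometry", fromlist=["Point"]).Point(pt)):
                ph.tissue_at(pt)  # raises if no region covers the point
                hits += 1
        assert hits > 100

    def test_target_center_tissue_is_blood(self):
        ph = insert_target(make_head_phantom(), (0.0, 40.0), 20.0, 20.0)
        assert ph.tissue_at((0.0, 40.0)) == "blood"
        assert ph.background_tissue_at((0.0, 40.0)) == "white"


class TestStraightRayDelay:
    def test_skin_surface_point_air_only(self):
        ph = make_head_phantom()
        ant = np.array([120.0, 0.0])
        pt = np.array([89.99, 0.0])
        tau = straight_ray_delay(ant, pt, ph)
        assert tau == pytest.approx(np.linalg.norm(ant - pt) / C0_MM, rel=2e-3)

    def test_homogeneous_interior_closed_form(self):
        # single-tissue degenerate check via a deep white-matter stretch
        ph = make_head_phantom()
        a, b_pt = np.array([0.0, 20.0]), np.array([0.0, -20.0])
        tau_ab = straight_ray_delay(np.array([0.0, 130.0]), b_pt, ph) - straight_ray_delay(
            np.array([0.0, 130.0]), a, ph
        )
        eps_white = m.tissue_permittivity("white", 1.6e9)
        assert tau_ab == pytest.approx(40.0 * np.sqrt(eps_white) / C0_MM, rel=1e-3)

    def test_layered_against_fine_numerical_integral(self):
        ph = insert_target(make_head_phantom(), (0.0, 40.0), 20.0, 20.0)
        ant = np.array([0.0, 130.0])
        pt = np.array([10.0, -30.0])
        tau = straight_ray_delay(ant, pt, ph)
        # numerical line integral at 0.02 mm steps
        n_steps = int(np.linalg.norm(pt - ant) / 0.02)
        ts = (np.arange(n_steps) + 0.5) / n_steps
        total = 0.0
        seg_len = np.linalg.norm(pt - ant) / n_steps
        for t in ts:
            x = ant + t * (pt - ant)
            if ph.outer_polygon.covers(__import__("shapely.geometry", fromlist=["Point"]).Point(x)):
                total += seg_len * np.sqrt(
                    m.tissue_permittivity(ph.tissue_at(x), 1.6e9, ph.tissues)
                )
            else:
                total += seg_len
        assert tau == pytest.approx(total / C0_MM, rel=1e-3)

    def test_point_outside_rejected(self):
        ph = make_head_phantom()
        with pytest.raises(ValueError):
            straight_ray_delay((120.0, 0.0), (200.0, 0.0), ph)


class TestForwardModel:
    def test_no_target_no_jitter_cancels_exactly(self, base_phantom, study_geometry):
        data = simulate_reflection(
            base_phantom, study_geometry, m.FrequencySweep(), ForwardConfig(seed=0)
        )
        ts = m.to_time_domain(data)
        scat = m.adjacent_average_subtract(ts)
        e_raw = np.sum(np.abs(ts.samples) ** 2)
        e_res = np.sum(np.abs(scat.samples) ** 2)
        assert e_res < 1e-10 * e_raw

    def test_target_echo_placed_at_straight_ray_delay(
        self, target_phantom, clean_dataset, study_geometry
    ):
        ts = m.to_time_domain(clean_dataset)
        scat = m.adjacent_average_subtract(ts)
        ctr = np.array(target_phantom.target.center)
        range_sample = 1.0 / (clean_dataset.sweep.df * clean_dataset.sweep.n_samples)
        for n in (0, 8, 16, 24):
            tau2 = 2.0 * straight_ray_delay(
                study_geometry.positions[n], ctr, target_phantom, f=1.6e9
            )
            k_peak = int(np.argmax(np.abs(scat.samples[n])))
            assert abs(k_peak * ts.dt - tau2) <= range_sample

    def test_bit_identical_under_fixed_seed(self, base_phantom, study_geometry):
        ph = dataclasses.replace(base_phantom, skin_jitter_sd=0.5)
        cfg = ForwardConfig(seed=9, n_clutter=3, clutter_amp=0.01)
        a = simulate_reflection(ph, study_geometry, m.FrequencySweep(), cfg)
        b = simulate_reflection(ph, study_geometry, m.FrequencySweep(), cfg)
        assert np.array_equal(a.s11, b.s11)

    def test_superposition_of_target_echo(self, base_phantom, study_geometry):
        sweep = m.FrequencySweep()
        cfg = ForwardConfig(seed=4)
        with_t = simulate_reflection(
            insert_target(base_phantom, (0.0, 40.0), 20.0, 20.0), study_geometry, sweep, cfg
        )
        without = simulate_reflection(base_phantom, study_geometry, sweep, cfg)
        only_t = simulate_reflection(
            insert_target(base_phantom, (0.0, 40.0), 20.0, 20.0),
            study_geometry, sweep,
            dataclasses.replace(cfg, include_skin_echo=False),
        )
        assert np.allclose(with_t.s11, without.s11 + only_t.s11, atol=1e-15)
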