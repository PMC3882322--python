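"""Optical dissector counting rules, total estimator, and the 2D nucleator."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from stereosim.cohort import CohortSpec, LognormalMixture, TissueModel, generate_tissue
from stereosim.errors import ConfigurationError
from stereosim.estimators import (
    CircularProfile,
    EllipseProfile,
    SamplingDesign,
    count_dissector,
    equatorial_profile,
    estimate_total,
    measure_nucleator,
)
from stereosim.microscopy import (
    FrameGrid,
    SamplingGeometry,
    Section,
    SectionPlan,
    place_frames,
    take_sections,
)


def design_full():
    """ssf = asf = tsf = 1: the estimate must equal the truth exactly."""
    return SamplingDesign(ssf=1.0, asf=1.0, tsf=1.0,
                          section_thickness=40.0, dissector_height=40.0, guard_zone=0.0)


def make_section(positions, z0=0.0, z1=40.0, extent_xy=(1000.0, 1000.0)):
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    return Section(index=0, z0=z0, z1=z1, positions=pos,
                   volumes=np.arange(1, pos.shape[0] + 1, dtype=float),
                   extent_xy=extent_xy)


class TestCountingRules:
    DESIGN = SamplingDesign(ssf=1.0, asf=0.0064, tsf=0.5,
                            section_thickness=40.0, dissector_height=20.0, guard_zone=2.0)
    FRAME = np.array([[10.0, 10.0, 50.0, 50.0]])

    def test_left_edge_excluded(self):
        section = make_section([[10.0, 30.0, 10.0]])  # on the exclusion line
        assert count_dissector(section, self.FRAME, self.DESIGN).sum_Q == 0

    def test_bottom_edge_excluded(self):
        section = make_section([[30.0, 10.0, 10.0]])
        assert count_dissector(section, self.FRAME, self.DESIGN).sum_Q == 0

    def test_right_and_top_edges_included(self):
        section = make_section([[50.0, 30.0, 10.0], [30.0, 50.0, 10.0]])
        assert count_dissector(section, self.FRAME, self.DESIGN).sum_Q == 2

    def test_interior_point_counted(self):
        section = make_section([[30.0, 30.0, 10.0]])
        result = count_dissector(section, self.FRAME, self.DESIGN)
        assert result.sum_Q == 1
        assert result.counted_volumes.tolist() == [1.0]

    def test_guard_zone_excludes(self):
        # depth window is [guard, guard + height) = [2, 22)
        section = make_section([[30.0, 30.0, 1.0], [30.0, 30.0, 2.0],
                                [30.0, 30.0, 21.9], [30.0, 30.0, 22.0]])
        assert count_dissector(section, self.FRAME, self.DESIGN).sum_Q == 2

    def test_brute_force_oracle(self, rng):
        """Vectorized tally equals an independent scalar rule application."""
        design = self.DESIGN
        for _ in range(20):
            pos = rng.random((30, 3)) * np.array([200.0, 200.0, 40.0])
            section = make_section(pos, extent_xy=(200.0, 200.0))
            grid = FrameGrid.random(40.0, 100.0, rng)
            frames = place_frames(section, grid)
            expected = 0
            for x, y, z in pos:  # independent, deliberately naive
                depth_ok = design.guard_zone <= z < design.guard_zone + design.dissector_height
                in_any = False
                for x0, y0, x1, y1 in frames:
                    if x0 < x <= x1 and y0 < y <= y1:
                        in_any = True
                if depth_ok and in_any:
                    expected += 1
            assert count_dissector(section, frames, design).sum_Q == expected


class TestEstimateTotal:
    def test_zero_tally(self):
        assert estimate_total(0, design_full()) == 0

    def test_hand_arithmetic(self):
        d1 = SamplingDesign(ssf=1 / 12, asf=0.0064, tsf=1.0,
                            section_thickness=40, dissector_height=40, guard_zone=0)
        assert estimate_total(384, d1) == pytest.approx(720000)
        d2 = SamplingDesign(ssf=1 / 12, asf=0.0064, tsf=0.5,
                            section_thickness=40, dissector_height=20, guard_zone=2)
        assert estimate_total(384, d2) == pytest.approx(1440000)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ConfigurationError):
            SamplingDesign(ssf=1.2, asf=0.0064, tsf=0.5,
                           section_thickness=40, dissector_height=20, guard_zone=2)

    def test_guard_zones_must_fit(self):
        with pytest.raises(ConfigurationError):
            SamplingDesign(ssf=1.0, asf=1.0, tsf=1.0,
                           section_thickness=40, dissector_height=40, guard_zone=5)


class TestTilingOracle:
    def test_full_fractions_recover_truth_exactly(self):
        """With frames tiling the plane and full depth/section sampling the
        forbidden-line rules count every point exactly once."""
        mixture = LognormalMixture((1.0,), (600.0,), (0.3,))
        design = design_full()
        rng = np.random.default_rng(0)
        for rep in range(100):
            n = int(rng.integers(20, 200))
            spec = CohortSpec("wt", 12, 1, n, between_animal_cv=0.0,
                              size_distribution=mixture,
                              extent=(300.0, 300.0, 120.0), seed=rep)
            tissue = generate_tissue(spec, 0)
            plan = SectionPlan(z_extent=120.0, thickness=40.0, period=1,
                               random_start=0)
            grid = FrameGrid.random(100.0, 100.0, rng)
            sum_Q = 0
            for section in take_sections(tissue, plan):
                frames = place_frames(section, grid)
                sum_Q += count_dissector(section, frames, design).sum_Q
            assert estimate_total(sum_Q, design) == tissue.true_count

    def test_mean_estimate_unbiased_under_systematic_subsampling(self):
        """Conventional fractions (ssf=1/12, asf=0.0064, tsf=0.5): the mean
        estimate over 200 animals matches the true mean within 2 SEM."""
        from stereosim.pipeline import simulate_animal

        mean_count = 200000
        spec = CohortSpec("wt", 12, 200, mean_count, between_animal_cv=0.10, seed=7)
        n_hats = np.array([
            simulate_animal(spec, i, SamplingGeometry(), measure_volumes=False).N_hat
            for i in range(200)
        ])
        sem = n_hats.std(ddof=1) / np.sqrt(len(n_hats))
        assert abs(n_hats.mean() - mean_count) <= 2 * sem


class TestNucleator:
    def test_sphere_closed_form(self, rng):
        m = measure_nucleator(CircularProfile(6.2), n_rays=5, rng=rng)
        assert m.volume_estimate == pytest.approx((4 * math.pi / 3) * 6.2**3, rel=1e-12)

    def test_equatorial_profile_inverts_volume(self, rng):
        m = measure_nucleator(equatorial_profile(998.2), n_rays=5, rng=rng)
        assert m.volume_estimate == pytest.approx(998.2, rel=1e-12)

    def test_degenerate_point(self, rng):
        m = measure_nucleator(CircularProfile(0.0), n_rays=5, rng=rng)
        assert m.volume_estimate == 0.0

    def test_rotation_invariant_for_spheres(self):
        vals = [
            measure_nucleator(CircularProfile(4.0), rng=np.random.default_rng(s)).volume_estimate
            for s in range(5)
        ]
        assert np.ptp(vals) == 0

    @given(scale=st.floats(0.1, 10.0), radius=st.floats(0.1, 20.0))
    def test_cubic_homogeneity(self, scale, radius):
        rng_a, rng_b = np.random.default_rng(1), np.random.default_rng(1)
        base = measure_nucleator(CircularProfile(radius), rng=rng_a).volume_estimate
        scaled = measure_nucleator(CircularProfile(scale * radius), rng=rng_b).volume_estimate
        assert scaled == pytest.approx(scale**3 * base, rel=1e-9)

    def test_spheroid_mean_near_truth(self, rng):
        # quick unbiasedness check; the high-precision version runs in the
        # acceptance suite at 1e5 draws
        a, b, c = 8.0, 5.0, 5.0
        truth = (4 * math.pi / 3) * a * b * c
        draws = 20000
        est = np.empty(draws)
        for i in range(draws):
            profile = EllipseProfile.spheroid_section(a, b, c, rng)
            est[i] = measure_nucleator(profile, n_rays=5, rng=rng).volume_estimate
        assert abs(est.mean() - truth) / truth < 0.03

    def test_positive_for_positive_area(self, rng):
        profile = EllipseProfile.spheroid_section(3.0, 2.0, 1.0, rng)
        assert measure_nucleator(profile, rng=rng).volume_estimate > 0

    def test_bad_ray_count(self, rng):
        with pytest.raises(ConfigurationError):
            measure_nucleator(CircularProfile(1.0), n_rays=0, rng=rng)
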