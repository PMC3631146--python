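"""Flow metrics vs closed-form oracles: averages, low-velocity and vortex areas."""

import numpy as np
import pytest
from scipy.optimize import brentq

from peribracket.errors import ConfigurationError
from peribracket.flow_metrics import (
    LOW_VELOCITY_THRESHOLD,
    RegionMetrics,
    SurfaceSpeedMap,
    combine_directions,
    detect_vortices,
    detect_vortices_tangential,
    low_velocity_area,
    near_wall_speed,
    regional_average_velocity,
    swallow_metrics,
    vortex_area_in_region,
)
from peribracket.flow_solver import MM
from peribracket.geometry import REGION_CODES, build_domain
from peribracket.synthetic_data import analytic_field, lamb_oseen_speed

from conftest import obstacle_free_model


@pytest.fixture(scope="module")
def fine_flat_model():
    """Obstacle-free 10 x 10 mm surface at 0.05 mm (vortex oracle grid)."""
    return obstacle_free_model(10.0, 10.0, 0.4, 0.05)


class TestNearWallSpeed:
    def test_uniform_field_gives_uniform_map(self, empty_model):
        fld = analytic_field("uniform", empty_model, velocity=(0, 0.04, 0))
        smap = near_wall_speed(fld, empty_model)
        assert np.allclose(smap.speeds, 0.04)

    def test_zero_field_gives_zero_map(self, empty_model):
        smap = near_wall_speed(analytic_field("uniform", empty_model,
                                              velocity=(0, 0, 0)), empty_model)
        assert np.all(smap.speeds == 0)

    def test_linear_shear_sampled_at_half_cell(self, empty_model):
        """u = alpha z sampled in the first layer equals alpha * h/2."""
        alpha = 10.0  # 1/s
        fld = analytic_field("shear", empty_model, alpha=alpha)
        smap = near_wall_speed(fld, empty_model)
        h = empty_model.cell_size * MM
        assert np.allclose(smap.speeds, alpha * h / 2)

    def test_solid_cells_excluded(self, default_model):
        fld = analytic_field("uniform", default_model, velocity=(0, 0.04, 0))
        smap = near_wall_speed(fld, default_model)
        assert np.isnan(smap.speeds[default_model.surface_solid]).all()


class TestRegionalAverage:
    def test_uniform_map(self, default_model):
        smap = SurfaceSpeedMap(
            np.full(default_model.shape[:2], 0.05), default_model.cell_area
        )
        avg = regional_average_velocity(smap, default_model)
        assert all(v == pytest.approx(0.05) for v in avg.values())

    def test_mirror_symmetric_map_equalizes_laterals(self, default_model):
        rng = np.random.default_rng(0)
        half = rng.uniform(0, 0.1, default_model.shape[:2])
        sym = 0.5 * (half + half[::-1, :])
        avg = regional_average_velocity(
            SurfaceSpeedMap(sym, default_model.cell_area), default_model
        )
        assert avg["BL"] == pytest.approx(avg["BR"], rel=1e-12)

    def test_random_map_equals_brute_force(self, default_model):
        rng = np.random.default_rng(3)
        speeds = rng.uniform(0, 0.2, default_model.shape[:2])
        avg = regional_average_velocity(
            SurfaceSpeedMap(speeds, default_model.cell_area), default_model
        )
        area = default_model.cell_area
        for site, code in REGION_CODES.items():
            total = n = 0.0
            for i in range(default_model.shape[0]):
                for j in range(default_model.shape[1]):
                    if default_model.region_labels[i, j] == code:
                        total += speeds[i, j] * area
                        n += area
            assert avg[site] == pytest.approx(total / n)


class TestLowVelocityArea:
    def test_uniform_above_threshold(self, default_model):
        smap = SurfaceSpeedMap(
            np.full(default_model.shape[:2], 0.01), default_model.cell_area
        )
        assert low_velocity_area(smap, default_model) == 0.0

    def test_uniform_below_threshold_gives_region_area(self, default_model):
        smap = SurfaceSpeedMap(
            np.full(default_model.shape[:2], 0.001), default_model.cell_area
        )
        a = low_velocity_area(smap, default_model, region="BG")
        assert a == pytest.approx(default_model.region_area(REGION_CODES["BG"]))

    def test_monotone_in_threshold(self, default_model):
        rng = np.random.default_rng(5)
        smap = SurfaceSpeedMap(
            rng.uniform(0, 0.02, default_model.shape[:2]),
            default_model.cell_area,
        )
        areas = [
            low_velocity_area(smap, default_model, threshold=t)
            for t in (0.001, 0.005, 0.01, 0.02)
        ]
        assert areas == sorted(areas)

    def test_lamb_oseen_matches_analytic_disc(self, fine_flat_model):
        """Counted area of the slow core equals the closed-form disc."""
        model = fine_flat_model
        gamma, r_core = 8.0e-5, 1.0
        fld = analytic_field(
            "lamb_oseen", model, center=(5.0, 5.0), gamma=gamma, r_core=r_core
        )
        r_in = brentq(
            lambda r: lamb_oseen_speed(r, gamma, r_core) - LOW_VELOCITY_THRESHOLD,
            1e-7, 1.1209 * r_core * MM,
        )
        x = model.domain.cell_centers(0)[:, None]
        y = model.domain.cell_centers(1)[None, :]
        inner = (x - 5.0) ** 2 + (y - 5.0) ** 2 <= 2.0**2  # well inside r_outer
        counted = low_velocity_area(
            near_wall_speed(fld, model), model, region=inner
        )
        analytic = np.pi * (r_in / MM) ** 2
        assert abs(counted - analytic) <= 2 * model.cell_area

    def test_nonpositive_threshold_rejected(self, default_model):
        smap = SurfaceSpeedMap(
            np.zeros(default_model.shape[:2]), default_model.cell_area
        )
        with pytest.raises(ConfigurationError):
            low_velocity_area(smap, default_model, threshold=0.0)


class TestDetectVortices:
    def test_uniform_flow_has_no_vortices(self, empty_model):
        fld = analytic_field("uniform", empty_model, velocity=(0.02, 0.03, 0))
        assert detect_vortices(fld, empty_model) == []

    def test_single_lamb_oseen_centroid(self, fine_flat_model):
        fld = analytic_field(
            "lamb_oseen", fine_flat_model, center=(5.0, 5.0),
            gamma=1e-4, r_core=1.0,
        )
        vortices = detect_vortices(fld, fine_flat_model)
        assert len(vortices) == 1
        cx, cy = vortices[0].centroid
        h = fine_flat_model.cell_size
        assert abs(cx - 5.0) <= h and abs(cy - 5.0) <= h

    def test_two_vortices_resolved(self, fine_flat_model):
        a = analytic_field(
            "lamb_oseen", fine_flat_model, center=(3.0, 3.0),
            gamma=1e-4, r_core=0.5,
        )
        b = analytic_field(
            "lamb_oseen", fine_flat_model, center=(7.0, 7.0),
            gamma=1e-4, r_core=0.5,
        )
        a.u += b.u
        a.v += b.v
        vortices = detect_vortices(a, fine_flat_model)
        assert len(vortices) == 2
        centers = sorted(v.centroid for v in vortices)
        h = fine_flat_model.cell_size
        assert abs(centers[0][0] - 3.0) <= h and abs(centers[0][1] - 3.0) <= h
        assert abs(centers[1][0] - 7.0) <= h and abs(centers[1][1] - 7.0) <= h

    def test_rotation_and_mirror_invariance(self, fine_flat_model):
        """Rotating the tangential field 90 deg rotates the detection."""
        model = fine_flat_model
        fld = analytic_field(
            "lamb_oseen", model, center=(3.0, 4.0), gamma=1e-4, r_core=0.8
        )
        uc = 0.5 * (fld.u[:-1] + fld.u[1:])[:, :, 0]
        vc = 0.5 * (fld.v[:, :-1] + fld.v[:, 1:])[:, :, 0]
        base = detect_vortices_tangential(uc, vc, model)

        # rigid 90 deg rotation: (x,y)->(-y,x), (u,v)->(-v,u)
        uc_r = -np.rot90(vc, k=1)
        vc_r = np.rot90(uc, k=1)
        rot = detect_vortices_tangential(uc_r, vc_r, model)
        assert len(rot) == len(base) == 1
        assert rot[0].area == pytest.approx(base[0].area)
        bx, by = base[0].centroid
        rx, ry = rot[0].centroid
        assert rx == pytest.approx(10.0 - by, abs=1e-9)
        assert ry == pytest.approx(bx, abs=1e-9)

        # mirror x -> -x flips the swirl sense but not |Q|
        mir = detect_vortices_tangential(-uc[::-1, :], vc[::-1, :], model)
        assert len(mir) == 1
        assert mir[0].area == pytest.approx(base[0].area)
        assert mir[0].centroid[0] == pytest.approx(10.0 - bx, abs=1e-9)
        assert mir[0].centroid[1] == pytest.approx(by, abs=1e-9)


class TestCombineDirections:
    def _metrics(self, site="BG", direction="gingival", **kw):
        base = dict(avg_speed=0.05, low_velocity_area=2.0, vortex_area=1.0)
        base.update(kw)
        return RegionMetrics(site=site, direction=direction, **base)

    def test_identical_inputs_identity(self):
        g = self._metrics()
        o = self._metrics(direction="occlusal")
        c = combine_directions(g, o)
        assert (c.avg_speed, c.low_velocity_area, c.vortex_area) == (
            0.05, 2.0, 1.0)
        assert c.direction == "combined"

    def test_areas_average(self):
        c = combine_directions(
            self._metrics(low_velocity_area=2.0),
            self._metrics(direction="occlusal", low_velocity_area=3.0),
        )
        assert c.low_velocity_area == pytest.approx(2.5)

    def test_zero_vortices_combine_to_zero(self):
        c = combine_directions(
            self._metrics(vortex_area=0.0),
            self._metrics(direction="occlusal", vortex_area=0.0),
        )
        assert c.vortex_area == 0.0

    def test_site_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            combine_directions(
                self._metrics(site="BO"), self._metrics(site="BG"))


class TestSwallowMetrics:
    def test_partition_property_of_low_velocity_areas(
        self, coarse_gingival_result, coarse_model
    ):
        """Site areas sum to at most the whole-surface low-velocity area."""
        smap = SurfaceSpeedMap(
            coarse_gingival_result.max_surface_speed, coarse_model.cell_area
        )
        whole = low_velocity_area(smap, coarse_model)
        by_site = sum(
            low_velocity_area(smap, coarse_model, region=s)
            for s in ("BO", "BG", "BL", "BR")
        )
        assert by_site <= whole + coarse_model.cell_area

    def test_vortex_in_bg_only_under_gingival_flow(
        self, gingival_result, default_model
    ):
        residual = gingival_result.snapshots[-1]
        in_bg = detect_vortices(residual, default_model, region="BG")
        in_bo = detect_vortices(residual, default_model, region="BO")
        assert len(in_bg) >= 1
        assert len(in_bo) == 0

    def test_swallow_metrics_shape(self, coarse_gingival_result, coarse_model):
        rows = swallow_metrics(coarse_gingival_result, coarse_model)
        assert [m.site for m in rows] == ["BO", "BG", "BL", "BR"]
        for m in rows:
            area = coarse_model.region_area(REGION_CODES[m.site])
            assert 0 <= m.low_velocity_area <= area
            assert 0 <= m.vortex_area <= area
            assert m.avg_speed >= 0
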