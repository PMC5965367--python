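"""Monte Carlo transport: source sampling, collimator trace, phantom dose."""

import math

import numpy as np
import pytest

from mrtsim.config import default_config
from mrtsim.geometry import CollimatorSpec, PhantomSpec, SourceModel
from mrtsim.materials import get_material, klein_nishina_mean_scattered_fraction
from mrtsim.spectrum import Spectrum
from mrtsim.transport import (
    DoseGrid,
    HeelModel,
    PhotonBatch,
    PhotonState,
    TransportError,
    make_dose_grids,
    normalize_to_reference,
    run_simulation,
    sample_compton,
    sample_source,
    trace_collimator,
    transport_phantom,
)

COLL = CollimatorSpec()
MONO80 = Spectrum(np.array([80.0]), np.array([1.0]))


def _mono_source(rng, n, src=None, **kw):
    src = src or SourceModel()
    return sample_source(src, COLL, rng, n, spectrum=MONO80, **kw)


class TestPhotonState:
    def test_unit_direction_enforced(self):
        with pytest.raises(TransportError):
            PhotonState((0, 0, 0), (0, 0, 2.0), 50.0, 1.0)
        s = PhotonState((0, 0, 0), (0, 0, 1.0), 50.0, 1.0)
        assert s.energy == 50.0

    def test_batch_scalar_view_round_trips(self, rng):
        b = _mono_source(rng, 10)
        s = b.state(3)
        assert s.statistical_weight == b.weight[3]
        assert np.allclose(s.direction, b.dir[3])


class TestSampleSource:
    def test_point_source_emits_from_one_point(self, rng):
        b = _mono_source(rng, 1000, src=SourceModel(focal_spot_width=0.0))
        assert np.all(b.pos[:, 0] == 0.0) and np.all(b.pos[:, 2] == 0.0)

    def test_uniform_spot_lateral_spread(self, rng):
        b = _mono_source(rng, 1_000_000)
        sd = b.pos[:, 0].std()
        expected = 0.4 / math.sqrt(12)
        se = expected / math.sqrt(2 * 1_000_000)  # SD of a sample SD
        assert abs(sd - expected) < 5 * se
        assert np.abs(b.pos[:, 0]).max() <= 0.2 + 1e-12

    def test_importance_weights_reproduce_cone_solid_angle(self, rng):
        # uniform-face sampling only: mean weight must equal the fractional
        # solid angle of the sampled exit-plane patch, computed here by an
        # independent 2D quadrature
        src = SourceModel(focal_spot_width=0.0)
        span, half_len, z = 12.0, 10.0, 75.0
        b = sample_source(src, COLL, rng, 400_000, spectrum=MONO80,
                          aperture_fraction=0.0, span_mm=span)
        xs = np.linspace(-span, span, 801)
        ys = np.linspace(-half_len, half_len, 801)
        xx, yy = np.meshgrid(xs, ys, indexing="ij")
        r2 = xx**2 + yy**2 + z**2
        integrand = z / r2**1.5  # cos(theta) / r^2
        omega = np.trapezoid(np.trapezoid(integrand, ys, axis=1), xs)
        expected = omega / (4 * np.pi)
        mean_w = b.weight.mean()
        assert mean_w == pytest.approx(expected, rel=5e-3)

    def test_heel_filtration_favours_anode_far_side(self, rng):
        src = SourceModel(focal_spot_width=0.0)
        heel = HeelModel(production_depth_um=8.2)
        b = sample_source(src, COLL, rng, 200_000, spectrum=MONO80,
                          heel=heel, aperture_fraction=0.0)
        pos_x = b.dir[:, 0] > 0.05
        neg_x = b.dir[:, 0] < -0.05
        # rays toward the anode (-x, low beam numbers) are attenuated more
        assert b.weight[pos_x].mean() > b.weight[neg_x].mean() * 1.02

    def test_line_focus_track_has_vertical_extent(self, rng):
        b = _mono_source(rng, 10_000)
        assert b.pos[:, 2].std() > 0.1  # mm, tilted focal track
        flat = _mono_source(rng, 10_000,
                            src=SourceModel(line_focus=False))
        assert np.all(flat.pos[:, 2] == 0.0)


class TestTraceCollimator:
    def test_axial_ray_in_central_slit_unattenuated(self, rng):
        b = PhotonBatch(
            pos=np.array([[0.0, 0.0, 0.0]]),
            dir=np.array([[0.0, 0.0, 1.0]]),
            energy=np.array([80.0]),
            weight=np.array([1.0]),
        )
        out, div = trace_collimator(b, _slits(), COLL, rng=rng,
                                    roulette_threshold=0.0)
        assert out.weight[0] == pytest.approx(1.0, rel=1e-12)
        assert div.delta_alpha_arcmin[0] == pytest.approx(0.0, abs=1e-9)

    def test_ray_through_solid_tungsten_closed_form(self, rng):
        # aimed at the dead centre between two slits: full 5 mm of W
        s = 0.2 / 75.0  # toward x = 200 um at the exit plane
        d = np.array([[s, 0.0, 1.0]])
        d /= np.linalg.norm(d)
        b = PhotonBatch(np.zeros((1, 3)), d, np.array([100.0]),
                        np.array([1.0]))
        out, _ = trace_collimator(b, _slits(), COLL, rng=rng,
                                  roulette_threshold=0.0)
        mu = get_material("W").mu_mm(100.0)
        path = 5.0 / d[0, 2]
        assert out.weight[0] == pytest.approx(np.exp(-mu * path), rel=1e-6)
        assert out.weight[0] < 1e-18

    def test_point_source_divergence_bounded_by_slit_acceptance(self, rng):
        src = SourceModel(focal_spot_width=0.0)
        b = sample_source(src, COLL, rng, 200_000, spectrum=MONO80)
        out, div = trace_collimator(b, _slits(), COLL, rng=rng)
        strong = out.weight > 0.5 * np.median(out.weight)
        half_acc = math.degrees(math.atan(50e-3 / 5.0)) * 60 / 2  # ~17'
        assert np.percentile(np.abs(div.delta_alpha_arcmin[strong]), 99.9) \
            <= half_acc * 1.1

    def test_collimator_shadow_with_point_source(self, rng):
        # photons carrying more than the bulk-leakage weight exit within a
        # slit aperture
        src = SourceModel(focal_spot_width=0.0)
        b = sample_source(src, COLL, rng, 100_000, spectrum=MONO80)
        out, div = trace_collimator(b, _slits(), COLL, rng=rng,
                                    roulette_threshold=0.0)
        alive = out.weight > 1e-3 * np.max(out.weight)
        frac = np.abs(
            (div.exit_x_um[alive] + 200.0) % 400.0 - 200.0
        )
        assert np.all(frac <= 25.0 + 1.0)

    def test_russian_roulette_is_unbiased(self, rng):
        src = SourceModel()
        b = sample_source(src, COLL, rng, 200_000, spectrum=MONO80)
        out_rr, _ = trace_collimator(
            b, _slits(), COLL, rng=np.random.default_rng(1),
            roulette_threshold=1e-2,
        )
        out_an, _ = trace_collimator(b, _slits(), COLL, rng=rng,
                                     roulette_threshold=0.0)
        w_rr, w_an = out_rr.weight.sum(), out_an.weight.sum()
        assert w_rr == pytest.approx(w_an, rel=0.02)


def _slits():
    from mrtsim.geometry import design_collimator

    return design_collimator(COLL)


class TestCompton:
    def test_mean_scattered_energy_matches_klein_nishina_quadrature(self, rng):
        n = 1_000_000
        frac, cos_t = sample_compton(np.full(n, 100.0), rng)
        expected = klein_nishina_mean_scattered_fraction(100.0)
        se = frac.std() / math.sqrt(n)
        assert abs(frac.mean() - expected) < 3 * se
        # kinematics: energy fraction consistent with sampled angle
        k = 100.0 / 510.99895
        assert np.allclose(frac, 1.0 / (1.0 + k * (1.0 - cos_t)), rtol=1e-9)

    def test_backscatter_fraction_reasonable(self, rng):
        _, cos_t = sample_compton(np.full(200_000, 60.0), rng)
        back = np.mean(cos_t < 0)
        assert 0.2 < back < 0.5


class TestTransportPhantom:
    def test_bare_source_follows_inverse_square(self, rng):
        # bare point source, no collimator: the weighted fluence through a
        # fixed central patch falls as 1/z^2
        src = SourceModel(focal_spot_width=0.0, line_focus=False)
        b = sample_source(src, COLL, rng, 2_000_000, spectrum=MONO80,
                          aperture_fraction=0.0)
        totals = []
        for z in (76.0, 80.0, 85.0):
            t = z / b.dir[:, 2]
            x = b.dir[:, 0] * t
            y = b.dir[:, 1] * t
            inside = (np.abs(x) < 1.6) & (np.abs(y) < 1.6)
            totals.append(np.sum(b.weight[inside] / b.dir[inside, 2]))
        for z, tot in zip((80.0, 85.0), totals[1:]):
            assert tot / totals[0] == pytest.approx((76.0 / z) ** 2,
                                                    rel=0.01)

    def test_vacuum_grid_scoring_scales_with_lateral_compression(self, rng):
        # the production grids integrate over y (infinite-slit convention):
        # the line-integrated central fluence of a bare cone scales as 1/z
        src = SourceModel(focal_spot_width=0.0, line_focus=False)
        b = sample_source(src, COLL, rng, 1_000_000, spectrum=MONO80,
                          aperture_fraction=0.0)
        grids = make_dose_grids(depths=(1.0, 5.0, 10.0))
        acc = transport_phantom(b, PhantomSpec(), grids, rng, vacuum=True,
                                splitting=1)
        lo, hi = 5000, len(grids[0].dose) - 5000  # central +-1.6 mm
        vals = acc[:, lo:hi].mean(axis=1)
        for i, d in enumerate((5.0, 10.0)):
            assert vals[i + 1] / vals[0] == pytest.approx(
                76.0 / (75.0 + d), rel=0.01
            )

    def test_primary_depth_attenuation_closed_form(self, rng):
        # broad parallel mono beam; primaries-only by killing at first
        # interaction (cutoff above the beam energy)
        n = 400_000
        x = rng.uniform(-11.0, 11.0, n)
        b = PhotonBatch(
            pos=np.stack([x, np.zeros(n), np.full(n, 75.0)], axis=1),
            dir=np.tile([0.0, 0.0, 1.0], (n, 1)),
            energy=np.full(n, 60.0),
            weight=np.ones(n),
        )
        grids = make_dose_grids(depths=(1.0, 10.0))
        acc = transport_phantom(b, PhantomSpec(), grids,
                                np.random.default_rng(5),
                                cutoff_kev=70.0, splitting=1)
        mat = get_material("PMMA")
        expected = math.exp(-mat.mu_mm(60.0) * 9.0)
        ratio = acc[1].sum() / acc[0].sum()
        assert ratio == pytest.approx(expected, rel=0.01)

    def test_scatter_buildup_increases_depth_dose(self, rng):
        n = 200_000
        x = rng.uniform(-11.0, 11.0, n)
        b = PhotonBatch(
            pos=np.stack([x, np.zeros(n), np.full(n, 75.0)], axis=1),
            dir=np.tile([0.0, 0.0, 1.0], (n, 1)),
            energy=np.full(n, 60.0),
            weight=np.ones(n),
        )
        grids = make_dose_grids(depths=(1.0, 10.0))
        full = transport_phantom(b, PhantomSpec(), grids,
                                 np.random.default_rng(6), splitting=1)
        mat = get_material("PMMA")
        narrow = math.exp(-mat.mu_mm(60.0) * 9.0)
        assert full[1].sum() / full[0].sum() > narrow

    def test_invalid_cutoff_rejected(self, rng):
        b = _mono_source(rng, 10)
        with pytest.raises(TransportError):
            transport_phantom(b, PhantomSpec(), make_dose_grids(), rng,
                              cutoff_kev=0.0)

    def test_scoring_depth_outside_phantom_rejected(self, rng):
        b = _mono_source(rng, 10)
        grids = make_dose_grids(depths=(60.0,))
        with pytest.raises(TransportError):
            transport_phantom(b, PhantomSpec(standoff=0.0), grids, rng)


class TestRunSimulation:
    def test_zero_histories_yield_empty_grids(self):
        cfg = default_config(**{"transport.histories": 0})
        res = run_simulation(cfg)
        assert res.histories == 0
        assert all(np.all(g.dose == 0) for g in res.grids)

    def test_same_seed_reproduces_bitwise(self):
        cfg = default_config(
            **{"transport.histories": 50_000, "transport.chunks": 2}
        )
        a = run_simulation(cfg)
        b = run_simulation(cfg)
        for ga, gb in zip(a.grids, b.grids):
            assert np.array_equal(ga.dose, gb.dose)
            assert np.array_equal(ga.variance, gb.variance)
        assert np.array_equal(a.divergence.exit_x_um, b.divergence.exit_x_um)

    def test_divergence_spread_bounded_by_slit_acceptance(self):
        # extended 0.4 mm spot: the per-slit angular spread around the slit
        # axis must stay within the slit acceptance arctan(50 um / 5 mm)
        cfg = default_config(
            **{"transport.histories": 100_000, "transport.chunks": 2}
        )
        res = run_simulation(cfg)
        full_width = math.degrees(math.atan(50e-3 / 5.0)) * 60  # ~34'
        spread = np.percentile(res.divergence.delta_alpha_arcmin, 99.5) - \
            np.percentile(res.divergence.delta_alpha_arcmin, 0.5)
        assert spread <= full_width * 1.1
        assert spread > full_width * 0.4
        # a point source collapses the spread to slit-width / source distance
        cfg_pt = default_config(
            **{"transport.histories": 50_000, "transport.chunks": 2,
               "source.focal_spot_width_mm": 0.0}
        )
        res_pt = run_simulation(cfg_pt)
        assert np.percentile(
            np.abs(res_pt.divergence.delta_alpha_arcmin), 99.0
        ) < 3.0


class TestNormalization:
    def _grids(self):
        cfg = default_config(
            **{"transport.histories": 300_000, "transport.chunks": 3}
        )
        return run_simulation(cfg).grids

    def test_reference_peak_and_ratio_invariance(self):
        from mrtsim.metrics import compute_metrics, detect_beams

        grids = self._grids()
        normed = normalize_to_reference(grids, 1.0, 300.0)
        prof = normed[0].to_profile()
        m = compute_metrics(prof, detect_beams(prof, 400.0))
        assert m.field["mean_peak"] == pytest.approx(300.0, rel=1e-9)

        m0 = compute_metrics(
            grids[1].to_profile(),
            detect_beams(grids[1].to_profile(), 400.0),
        )
        m1 = compute_metrics(
            normed[1].to_profile(),
            detect_beams(normed[1].to_profile(), 400.0),
        )
        assert m1.field["field_pvdr"] == pytest.approx(
            m0.field["field_pvdr"], rel=1e-9
        )
        doubled = normalize_to_reference(grids, 1.0, 600.0)
        assert np.allclose(doubled[2].dose, 2 * normed[2].dose)

    def test_missing_reference_depth_rejected(self):
        grids = make_dose_grids(depths=(1.0,))
        with pytest.raises(TransportError):
            normalize_to_reference(grids, 7.0, 300.0)
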