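import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardiodti import (
    PhantomSpec,
    WallFrame,
    compute_index_maps,
    compute_wall_frame,
    e2_angle,
    eigen_decompose,
    fit_tensor_loglinear,
    fractional_anisotropy,
    ha_transmural_gradient,
    helix_angle,
    make_dataset,
    mean_diffusivity,
    slice_summary,
    transverse_angle,
)
from cardiodti.errors import AnalysisError
from cardiodti.tensor import EigenSystem


def unit_frame(n=1):
    """Frame with radial=+x, circumferential=+y, longitudinal=+z per voxel."""
    shape = (n, 1, 1)
    e = np.zeros(shape + (3,))
    rad, circ, lon = e.copy(), e.copy(), e.copy()
    rad[..., 0] = 1.0
    circ[..., 1] = 1.0
    lon[..., 2] = 1.0
    mask = np.ones(shape, bool)
    depth = np.linspace(0.05, 0.95, n).reshape(shape)
    from cardiodti import ring_partition

    return WallFrame(rad, circ, lon, depth, ring_partition(depth), mask, mask.copy())


def eigsys(evals, evecs_cols, n=1):
    """EigenSystem with the same eigensystem replicated over n voxels."""
    shape = (n, 1, 1)
    evals_a = np.broadcast_to(np.asarray(evals, float), shape + (3,)).copy()
    evecs_a = np.broadcast_to(np.asarray(evecs_cols, float), shape + (3, 3)).copy()
    mask = np.ones(shape, bool)
    return EigenSystem(evals_a, evecs_a, mask, mask.copy(), np.zeros(shape, bool))


class TestScalarIndices:
    @pytest.mark.parametrize(
        "evals,expected",
        [((1e-3, 1e-3, 1e-3), 1e-3), ((1.7e-3, 0.3e-3, 0.1e-3), 0.7e-3), ((0, 0, 0), 0.0)],
    )
    def test_mean_diffusivity(self, evals, expected):
        e = eigsys(evals, np.eye(3))
        assert mean_diffusivity(e)[0, 0, 0] == pytest.approx(expected, abs=1e-18)

    def test_fa_isotropic_zero_and_rank1_one(self):
        assert fractional_anisotropy(eigsys((1e-3, 1e-3, 1e-3), np.eye(3)))[0, 0, 0] == 0.0
        assert fractional_anisotropy(eigsys((1.0, 0.0, 0.0), np.eye(3)))[0, 0, 0] == pytest.approx(1.0)

    def test_fa_closed_form(self):
        # independent evaluation of FA = sqrt(3/2)*||L-MD||/||L|| for (1.7,.3,.1)e-3
        l1, l2, l3 = 1.7e-3, 0.3e-3, 0.1e-3
        md = (l1 + l2 + l3) / 3
        expected = math.sqrt(1.5) * math.sqrt(
            (l1 - md) ** 2 + (l2 - md) ** 2 + (l3 - md) ** 2
        ) / math.sqrt(l1**2 + l2**2 + l3**2)
        assert expected == pytest.approx(0.873, abs=5e-4)
        got = fractional_anisotropy(eigsys((l1, l2, l3), np.eye(3)))[0, 0, 0]
        assert got == pytest.approx(expected, rel=1e-12)

    def test_fa_zero_tensor_convention(self):
        assert fractional_anisotropy(eigsys((0, 0, 0), np.eye(3)))[0, 0, 0] == 0.0


class TestAngleMaps:
    def test_helix_angle_examples(self):
        f = unit_frame()
        circ, lon, rad = f.circumferential, f.longitudinal, f.radial
        ha, ok = helix_angle(circ, f)
        assert ha[0, 0, 0] == pytest.approx(0.0, abs=1e-9)
        ha, _ = helix_angle((circ + lon) / math.sqrt(2), f)
        assert ha[0, 0, 0] == pytest.approx(45.0, abs=1e-9)
        # radial component is projected out
        ha, _ = helix_angle((circ + rad) / math.sqrt(2), f)
        assert ha[0, 0, 0] == pytest.approx(0.0, abs=1e-9)
        # E1 ~ radial: projection degenerate -> invalid
        _, ok = helix_angle(rad, f)
        assert not ok[0, 0, 0]

    def test_transverse_angle_examples(self):
        f = unit_frame()
        circ, rad, lon = f.circumferential, f.radial, f.longitudinal
        ta, _ = transverse_angle(circ, f)
        assert ta[0, 0, 0] == pytest.approx(0.0, abs=1e-9)
        ta, _ = transverse_angle((circ + rad) / math.sqrt(2), f)
        assert ta[0, 0, 0] == pytest.approx(45.0, abs=1e-9)
        _, ok = transverse_angle(lon, f)
        assert not ok[0, 0, 0]

    def test_e2_angle_examples(self):
        f = unit_frame()
        circ, rad, lon = f.circumferential, f.radial, f.longitudinal
        e1 = circ  # fiber along circumferential; cross-fiber tangent axis ~ longitudinal
        e2a, _ = e2_angle(e1, lon, f)
        assert e2a[0, 0, 0] == pytest.approx(0.0, abs=1e-9)
        e2a, _ = e2_angle(e1, rad, f)
        assert e2a[0, 0, 0] == pytest.approx(90.0, abs=1e-9)
        e2a, _ = e2_angle(e1, (lon + rad) / math.sqrt(2), f)
        assert e2a[0, 0, 0] == pytest.approx(45.0, abs=1e-9)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_sign_flip_invariance(self, seed):
        rng = np.random.default_rng(seed)
        f = unit_frame()
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        vv = np.broadcast_to(v, (1, 1, 1, 3))
        for fn in (lambda x: helix_angle(x, f), lambda x: transverse_angle(x, f)):
            a1, o1 = fn(vv)
            a2, o2 = fn(-vv)
            assert o1[0, 0, 0] == o2[0, 0, 0]
            if o1[0, 0, 0]:
                assert a1[0, 0, 0] == pytest.approx(a2[0, 0, 0], abs=1e-9)

    def test_angle_ranges_on_noisy_fit(self, default_protocol):
        spec = PhantomSpec(grid_shape=(32, 32, 1), inner_radius=6, outer_radius=14, snr=5.0, seed=9)
        ds = make_dataset(spec, default_protocol)
        tf = fit_tensor_loglinear(ds.signal, default_protocol, 1000.0, ds.mask)
        eigs = eigen_decompose(tf)
        frame = compute_wall_frame(ds.mask, spec.voxel_size)
        maps = compute_index_maps(eigs, frame)
        assert np.all((maps.fa[maps.valid_scalar] >= 0) & (maps.fa[maps.valid_scalar] <= 1))
        assert np.all((maps.e2a[maps.valid_e2a] >= 0) & (maps.e2a[maps.valid_e2a] <= 90))
        assert np.all(np.abs(maps.ha[maps.valid_ha]) <= 90)
        assert np.all(np.abs(maps.ta[maps.valid_ta]) <= 90)
        assert np.all(maps.md[maps.valid_scalar] >= 0)


class TestHaGradient:
    def test_ols_slope_of_ring_means(self):
        # 5 rings x 4 voxels with ring means (60, 30, 0, -30, -60)
        n = 20
        f = unit_frame(n)
        f.depth[...] = np.repeat([0.1, 0.3, 0.5, 0.7, 0.9], 4).reshape(n, 1, 1)
        from cardiodti import ring_partition

        f.ring = ring_partition(f.depth)
        ha = np.repeat([60.0, 30.0, 0.0, -30.0, -60.0], 4).reshape(n, 1, 1)
        ha += np.tile([-1.0, 1.0, -1.0, 1.0], 5).reshape(n, 1, 1)  # ring means unchanged
        ok = np.ones((n, 1, 1), bool)
        slope = ha_transmural_gradient(ha, ok, f, 0)
        assert slope == pytest.approx(-1.5, abs=1e-12)

    def test_constant_ha_zero_slope(self):
        n = 10
        f = unit_frame(n)
        ha = np.full((n, 1, 1), 17.0)
        slope = ha_transmural_gradient(ha, np.ones((n, 1, 1), bool), f, 0)
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_too_few_rings_raises(self):
        f = unit_frame(3)
        f.ring[...] = 2
        with pytest.raises(AnalysisError):
            ha_transmural_gradient(np.zeros((3, 1, 1)), np.ones((3, 1, 1), bool), f, 0)

    def test_phantom_ramp_recovered(self, default_protocol):
        spec = PhantomSpec()  # +60/-60 ramp
        ds = make_dataset(spec, default_protocol)
        tf = fit_tensor_loglinear(ds.signal, default_protocol, 1000.0, ds.mask)
        eigs = eigen_decompose(tf)
        frame = compute_wall_frame(ds.mask, spec.voxel_size)
        ha, ok = helix_angle(eigs.e1, frame)
        slope = ha_transmural_gradient(ha, ok, frame, 2)
        assert slope == pytest.approx(-1.2, abs=0.1)


class TestSliceSummary:
    def test_two_voxel_mean(self):
        e = eigsys((1e-3, 1e-3, 1e-3), np.eye(3), n=2)
        # give the two voxels different FA by editing eigenvalues
        e.evals[0, 0, 0] = [1.0e-3, 1.0e-3, 1.0e-3]
        e.evals[1, 0, 0] = [1.7e-3, 0.3e-3, 0.1e-3]
        f = unit_frame(2)
        maps = compute_index_maps(e, f)
        fa = maps.fa[maps.valid_scalar]
        assert np.mean(fa) == pytest.approx((fa[0] + fa[1]) / 2)

    def test_symmetric_ramp_mean_and_slope_decouple(self, default_protocol):
        spec = PhantomSpec()
        ds = make_dataset(spec, default_protocol)
        tf = fit_tensor_loglinear(ds.signal, default_protocol, 1000.0, ds.mask)
        eigs = eigen_decompose(tf)
        frame = compute_wall_frame(ds.mask, spec.voxel_size)
        maps = compute_index_maps(eigs, frame)
        summ = slice_summary(maps, frame, 2)
        ha_mean, _ = summ["HA"]
        grad, _ = summ["HA_gradient"]
        # voxelwise mean of the symmetric +/-60 ramp over an annulus is the
        # area-weighted ramp mean: 60 - 120 * E[depth], with
        # E[depth] = int t (ri + (ro-ri) t) dt / int r dr over the wall
        ri, ro = spec.inner_radius, spec.outer_radius
        e_depth = ((ro - ri) * (ri / 2 + (ro - ri) / 3)) / ((ro**2 - ri**2) / 2)
        expected_mean = 60.0 - 120.0 * e_depth
        assert ha_mean == pytest.approx(expected_mean, abs=1.5)
        assert abs(ha_mean) < 15.0  # small relative to the 60-degree ramp amplitude
        assert grad == pytest.approx(-1.2, abs=0.1)
        assert summ["MD"][0] == pytest.approx(0.7e-3, rel=1e-6)
        assert summ["E2A"][0] == pytest.approx(spec.e2a, abs=1e-6)

    def test_zero_helix_phantom_summary_ha_zero(self, default_protocol):
        spec = PhantomSpec(grid_shape=(32, 32, 1), inner_radius=6, outer_radius=14,
                           ha_endo=0.0, ha_epi=0.0)
        ds = make_dataset(spec, default_protocol)
        tf = fit_tensor_loglinear(ds.signal, default_protocol, 600.0, ds.mask)
        eigs = eigen_decompose(tf)
        frame = compute_wall_frame(ds.mask, spec.voxel_size)
        summ = slice_summary(compute_index_maps(eigs, frame), frame, 0)
        assert summ["HA"][0] == pytest.approx(0.0, abs=1e-6)
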