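"""Procrustes alignment, distance, GPA, midplane and reflection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from craniomorph.geometry import (
    DegenerateGeometryError,
    centroid_size,
    estimate_midplane,
    gpa,
    opa_align,
    procrustes_distance,
    reflect_and_relabel,
    shape_pca,
)
from craniomorph.landmarks import LandmarkConfiguration

from conftest import random_similarity


UNIT_SQUARE = np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]])


class TestCentroidSize:
    def test_unit_square(self):
        # four corners at distance sqrt(1/2) from the centre: CS = sqrt(2)
        assert centroid_size(UNIT_SQUARE) == pytest.approx(np.sqrt(2.0))

    def test_translation_invariance_and_homogeneity(self, rng):
        pts = rng.normal(size=(10, 3))
        cs = centroid_size(pts)
        assert centroid_size(pts + [5.0, -3.0, 2.0]) == pytest.approx(cs)
        assert centroid_size(2.0 * pts) == pytest.approx(2.0 * cs)

    def test_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            centroid_size(np.zeros((1, 3)))


class TestOPA:
    def test_exact_similarity_recovery(self, rng):
        src = rng.normal(size=(8, 3))
        xform_true = random_similarity(rng)
        tgt = xform_true.apply(src)
        xform, rms = opa_align(src, tgt)
        assert rms < 1e-10
        np.testing.assert_allclose(xform.apply(src), tgt, atol=1e-9)
        np.testing.assert_allclose(xform.rotation, xform_true.rotation,
                                   atol=1e-9)
        assert xform.scale == pytest.approx(xform_true.scale)

    def test_scaling_flag(self, rng):
        src = rng.normal(size=(6, 3))
        tgt = 2.0 * src
        _, rms_noscale = opa_align(src, tgt, allow_scaling=False)
        xform, rms_scale = opa_align(src, tgt, allow_scaling=True)
        assert rms_noscale > 1e-3
        assert rms_scale < 1e-10
        assert xform.scale == pytest.approx(2.0)

    def test_against_numeric_optimizer(self, rng):
        """OPA residual equals an independent minimization over explicitly
        parameterized rotations, scale and translation."""
        src = rng.normal(size=(6, 3))
        tgt = rng.normal(size=(6, 3))
        _, rms = opa_align(src, tgt)

        def objective(params):
            rotvec, log_s, t = params[:3], params[3], params[4:]
            R = Rotation.from_rotvec(rotvec).as_matrix()
            resid = np.exp(log_s) * src @ R.T + t - tgt
            return (resid ** 2).sum()

        best = np.inf
        for k in range(8):
            r0 = np.random.default_rng(k).normal(size=3)
            res = minimize(objective, np.concatenate([r0, [0.0], np.zeros(3)]),
                           method="Nelder-Mead",
                           options={"maxiter": 20000, "xatol": 1e-12,
                                    "fatol": 1e-14})
            best = min(best, res.fun)
        assert rms == pytest.approx(np.sqrt(best / len(src)), abs=1e-6)

    def test_count_mismatch(self, rng):
        with pytest.raises(ValueError):
            opa_align(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))


class TestProcrustesDistance:
    def test_identity_and_similarity_invariance(self, rng):
        a = rng.normal(size=(7, 3))
        assert procrustes_distance(a, a) == pytest.approx(0.0, abs=1e-12)
        xf = random_similarity(rng)
        assert procrustes_distance(a, xf.apply(a)) == pytest.approx(0.0, abs=1e-9)

    def test_square_vs_rectangle_oracle(self):
        """Planar square vs 2:1 rectangle, checked against a dense numeric
        rotation search on the size-normalized point sets."""
        square = UNIT_SQUARE
        rect = np.array([[0.0, 0, 0], [2, 0, 0], [2, 1, 0], [0, 1, 0]])
        d = procrustes_distance(square, rect)

        ca = (square - square.mean(0)) / centroid_size(square)
        cb = (rect - rect.mean(0)) / centroid_size(rect)

        def objective(rotvec):
            R = Rotation.from_rotvec(rotvec).as_matrix()
            return ((ca @ R.T - cb) ** 2).sum()

        best = np.inf
        for k in range(12):
            r0 = np.random.default_rng(k).normal(size=3)
            res = minimize(objective, r0, method="Nelder-Mead",
                           options={"maxiter": 20000, "xatol": 1e-12,
                                    "fatol": 1e-16})
            best = min(best, res.fun)
        assert d == pytest.approx(np.sqrt(best), abs=1e-6)

    def test_shared_subset(self, template_pack, rng):
        tpl, _, _ = template_pack
        a = tpl.copy()
        b = tpl.with_coords(tpl.coords + rng.normal(scale=0.5,
                                                    size=tpl.coords.shape))
        a.present[:10] = False
        b.present[-10:] = False
        assert procrustes_distance(a, b) > 0

    def test_too_few_shared(self, rng):
        with pytest.raises(DegenerateGeometryError):
            procrustes_distance(rng.normal(size=(2, 3)),
                                rng.normal(size=(2, 3)))


class TestGPA:
    def test_identical_inputs(self, rng):
        s = rng.normal(size=(10, 3))
        res = gpa([s.copy() for _ in range(5)])
        for a in res.aligned:
            np.testing.assert_allclose(a, res.consensus, atol=1e-12)
        assert res.converged

    def test_similarity_copies_collapse(self, rng):
        s = rng.normal(size=(9, 3))
        res = gpa([s, random_similarity(rng).apply(s)])
        for a in res.aligned:
            assert procrustes_distance(a, res.consensus) < 1e-9

    def test_consensus_conventions(self, rng):
        base = rng.normal(size=(8, 3)) * 10
        shapes = [base + rng.normal(scale=0.5, size=(8, 3)) for _ in range(6)]
        res = gpa(shapes)
        assert res.converged
        np.testing.assert_allclose(res.consensus.mean(axis=0), 0, atol=1e-9)
        assert centroid_size(res.consensus) == pytest.approx(1.0, abs=1e-8)
        # idempotence: GPA of aligned shapes barely moves the consensus
        res2 = gpa(res.aligned)
        assert procrustes_distance(res2.consensus, res.consensus) < 1e-7

    def test_consensus_recovers_template(self, template_pack, rng):
        tpl, _, _ = template_pack
        noise = 0.3
        shapes = [tpl.coords + rng.normal(scale=noise, size=tpl.coords.shape)
                  for _ in range(10)]
        res = gpa(shapes, scale=True)
        d = procrustes_distance(res.consensus, tpl.coords)
        assert d < 0.05  # well within the noise scale in shape units
        # residual SS matches direct recomputation from the aligned output
        X = np.array([a.ravel() for a in res.aligned])
        ss_direct = ((X - X.mean(axis=0)) ** 2).sum()
        ss_loop = sum(((a - np.mean(res.aligned, axis=0)) ** 2).sum()
                      for a in res.aligned)
        assert ss_direct == pytest.approx(ss_loop, rel=1e-12)


class TestShapePCA:
    def test_fractions_and_duplication(self, rng):
        shapes = [rng.normal(size=(6, 3)) for _ in range(8)]
        res = gpa(shapes)
        _, comps, frac = shape_pca(res)
        assert frac.sum() == pytest.approx(1.0, abs=1e-12)
        res2 = gpa(shapes + shapes)
        _, comps2, frac2 = shape_pca(res2)
        k = min(5, len(frac))
        np.testing.assert_allclose(frac2[:k], frac[:k], atol=1e-6)

    def test_two_shapes_single_component(self, rng):
        shapes = [rng.normal(size=(6, 3)) for _ in range(2)]
        res = gpa(shapes)
        with pytest.raises(ValueError):
            shape_pca(res)
        # two distinct shapes (one duplicated): a single axis of variation
        res3 = gpa([shapes[0], shapes[1], shapes[0]])
        _, _, frac = shape_pca(res3)
        assert frac[0] == pytest.approx(1.0, abs=1e-6)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(scale=st.floats(0.1, 10.0),
       tx=st.floats(-100, 100), ty=st.floats(-100, 100),
       tz=st.floats(-100, 100), angle=st.floats(-np.pi, np.pi))
def test_procrustes_distance_similarity_invariance_property(
        scale, tx, ty, tz, angle):
    """d(T(a), b) == d(a, b) for every similarity transform T."""
    rng = np.random.default_rng(99)
    a = rng.normal(size=(7, 3)) * 10
    b = a + rng.normal(size=(7, 3))
    d = procrustes_distance(a, b)
    R = Rotation.from_rotvec(angle * np.array([0.26, -0.72, 0.64])).as_matrix()
    a_t = scale * a @ R.T + np.array([tx, ty, tz])
    assert procrustes_distance(a_t, b) == pytest.approx(d, abs=1e-7)
    assert centroid_size(a_t) == pytest.approx(scale * centroid_size(a),
                                               rel=1e-9)


class TestMidplaneAndReflection:
    def test_planar_midline(self, template_pack):
        tpl, _, _ = template_pack
        plane = estimate_midplane(tpl)
        # template midline lies exactly in x = 0
        np.testing.assert_allclose(np.abs(plane.normal), [1, 0, 0], atol=1e-10)
        assert abs(plane.point[0]) < 1e-10

    def test_symmetric_fixed_point(self, template_pack):
        tpl, pairing, _ = template_pack
        plane = estimate_midplane(tpl)
        mirrored = reflect_and_relabel(tpl, plane, pairing)
        np.testing.assert_allclose(mirrored.coords, tpl.coords, atol=1e-8)

    def test_involution(self, template_pack, rng):
        tpl, pairing, _ = template_pack
        config = tpl.with_coords(tpl.coords
                                 + rng.normal(scale=2.0, size=tpl.coords.shape))
        plane = estimate_midplane(config)
        twice = reflect_and_relabel(
            reflect_and_relabel(config, plane, pairing), plane, pairing)
        np.testing.assert_allclose(twice.coords, config.coords, atol=1e-10)

    def test_mask_relabeling(self, template_pack):
        from craniomorph.landmarks import Side
        tpl, pairing, _ = template_pack
        config = tpl.copy()
        for i, d in enumerate(config.template):
            if d.side is Side.LEFT:
                config.present[i] = False
                config.coords[i] = np.nan
        config = LandmarkConfiguration(config.template, config.coords,
                                       config.present)
        plane = estimate_midplane(config)
        mirrored = reflect_and_relabel(config, plane, pairing)
        for i, d in enumerate(mirrored.template):
            if d.side is Side.RIGHT:
                assert not mirrored.present[i]
            elif d.side is Side.LEFT:
                assert mirrored.present[i]

    def test_collinear_midline_degenerate(self, template_pack):
        tpl, _, _ = template_pack
        config = tpl.copy()
        mid = [i for i, d in enumerate(config.template)
               if d.side.value == "midline"]
        config.coords[mid] = np.outer(np.arange(len(mid)), [0, 1.0, 0])
        with pytest.raises(DegenerateGeometryError):
            estimate_midplane(config)
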