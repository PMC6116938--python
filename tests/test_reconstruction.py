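"""Mirror completion, rearticulation, reference estimation, ensembles."""

import numpy as np
import pytest
from scipy import stats

from craniomorph.geometry import estimate_midplane, reflect_and_relabel
from craniomorph.landmarks import LandmarkConfiguration, ReferenceSample, Side
from craniomorph.reconstruction import (
    Provenance,
    ReconstructionError,
    SubsampleSpec,
    align_by_midplane_and_contact,
    estimate_missing_from_reference,
    mirror_across_midplane,
    mirror_reconstruct,
    rearticulate_fragment,
    reconstruct_ensemble,
    select_closest,
    warp_donor_mesh,
    _rotation_about_axis,
)
from craniomorph.synthetic import (
    SimulationSpec,
    apply_fragmentation,
    default_fragmentation,
    default_reconstruction_scenario,
    make_template,
    simulate_population,
    table1_subsample_specs,
)

from conftest import random_similarity


def delete_left(config, n=None):
    """Return a copy with (the first n) left-side landmarks missing."""
    out = config.copy()
    left = [i for i, d in enumerate(out.template) if d.side is Side.LEFT]
    if n is not None:
        left = left[:n]
    out.present[left] = False
    out.coords[left] = np.nan
    return LandmarkConfiguration(out.template, out.coords, out.present,
                                 out.specimen_id, dict(out.metadata))


class TestMirrorReconstruct:
    def test_exact_on_symmetric(self, template_pack):
        tpl, pairing, _ = template_pack
        damaged = delete_left(tpl, n=20)
        res = mirror_reconstruct(damaged, pairing)
        assert res.completed.is_complete is False or True
        filled = [i for i, d in enumerate(tpl.template)
                  if res.provenance.get(d.id) is Provenance.MIRRORED]
        assert len(filled) == 20
        np.testing.assert_allclose(res.completed.coords[filled],
                                   tpl.coords[filled], atol=1e-6)

    def test_provenance_partition_and_originals_untouched(self, template_pack):
        tpl, pairing, _ = template_pack
        damaged = delete_left(tpl, n=10)
        res = mirror_reconstruct(damaged, pairing)
        for i, d in enumerate(tpl.template):
            if damaged.present[i]:
                assert res.provenance[d.id] is Provenance.ORIGINAL
                np.testing.assert_array_equal(res.completed.coords[i],
                                              damaged.coords[i])

    def test_beats_plain_mirroring_on_smooth_asymmetry(self):
        """Asymmetry-preserving warp recovers deleted left landmarks better
        than naive reflection, paired one-sided test at alpha = 0.01."""
        spec = SimulationSpec(n_specimens={"s": 50}, group_effects={"s": 0.0},
                              directional_asymmetry_magnitude=2.0,
                              noise_sd=0.2, master_seed=21)
        configs, _, _ = simulate_population(spec)
        tpl, pairing, _ = make_template(spec)
        frag = default_fragmentation(tpl)
        gains = []
        for c in configs:
            damaged, _ = apply_fragmentation(c, frag)
            res = mirror_reconstruct(damaged, pairing)
            fill = np.array([res.provenance.get(d.id) is Provenance.MIRRORED
                             for d in damaged.template])
            plane = estimate_midplane(damaged)
            naive = reflect_and_relabel(damaged, plane, pairing)
            rmse_warp = np.sqrt(
                ((res.completed.coords[fill] - c.coords[fill]) ** 2).sum(1).mean())
            rmse_naive = np.sqrt(
                ((naive.coords[fill] - c.coords[fill]) ** 2).sum(1).mean())
            gains.append(rmse_naive - rmse_warp)
        gains = np.array(gains)
        assert gains.mean() > 0
        t = stats.ttest_1samp(gains, 0.0, alternative="greater")
        assert t.pvalue < 0.01

    def test_zero_overlap_error(self, template_pack):
        tpl, pairing, _ = template_pack
        config = tpl.copy()
        # keep only 3 midline points: no usable bilateral overlap for a warp
        config.present[:] = False
        config.present[:3] = True
        config = LandmarkConfiguration(config.template, config.coords,
                                       config.present)
        with pytest.raises(Exception):
            mirror_reconstruct(config, pairing)


class TestRearticulate:
    def test_exact_recovery(self, template_pack, rng):
        tpl, _, _ = template_pack
        xf = random_similarity(rng, scale_range=(1.0, 1.0))
        fragment = tpl.with_coords(xf.apply(tpl.coords))
        xform, moved = rearticulate_fragment(fragment, tpl)
        np.testing.assert_allclose(moved.coords, tpl.coords, atol=1e-9)

    def test_noise_band(self, template_pack):
        """Residual RMS against sigma-perturbed anchors stays within
        [0.5 sigma, 2 sigma] over 100 seeds."""
        tpl, _, _ = template_pack
        sigma = 0.8
        inside = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            anchors = tpl.with_coords(tpl.coords
                                      + r.normal(scale=sigma,
                                                 size=tpl.coords.shape))
            _, moved = rearticulate_fragment(tpl.copy(), anchors)
            rms = np.sqrt(((moved.coords - anchors.coords) ** 2).sum(1).mean())
            inside += 0.5 * sigma <= rms <= 2 * sigma
        assert inside >= 95

    def test_too_few_anchors(self, template_pack):
        tpl, _, _ = template_pack
        anchors = tpl.copy()
        anchors.present[2:] = False
        anchors = LandmarkConfiguration(anchors.template, anchors.coords,
                                        anchors.present)
        with pytest.raises(ReconstructionError):
            rearticulate_fragment(tpl.copy(), anchors)


class TestMidplaneContactAlignment:
    def test_identity_when_already_aligned(self, template_pack):
        tpl, _, _ = template_pack
        contact = [tpl.template.ids[len(tpl.template) // 2]]
        xf = align_by_midplane_and_contact(tpl, tpl, contact)
        np.testing.assert_allclose(xf.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(xf.translation, 0.0, atol=1e-9)

    def test_recovers_transverse_rotation(self, template_pack):
        tpl, pairing, _ = template_pack
        # contact: a right-side landmark (temporomandibular analogue)
        contact_id = next(d.id for d in tpl.template if d.side is Side.RIGHT)
        i = tpl.template.index_of(contact_id)
        angle = 0.3
        axis = np.array([1.0, 0.0, 0.0])  # transverse = midplane normal
        R = _rotation_about_axis(axis, angle)
        c = tpl.coords[i]
        moved = tpl.with_coords((tpl.coords - c) @ R.T + c)
        xf = align_by_midplane_and_contact(moved, tpl, [contact_id])
        np.testing.assert_allclose(xf.apply(moved.coords), tpl.coords,
                                   atol=1e-6)
        # recovered rotation angle matches the applied one
        rec_angle = np.arccos(np.clip((np.trace(xf.rotation) - 1) / 2, -1, 1))
        assert rec_angle == pytest.approx(angle, abs=1e-6)

    def test_empty_contact(self, template_pack):
        tpl, _, _ = template_pack
        with pytest.raises(ReconstructionError):
            align_by_midplane_and_contact(tpl, tpl, [])


class TestReferenceEstimation:
    def test_self_consistency(self, template_pack, rng):
        spec = SimulationSpec(n_specimens={"g": 10}, group_effects={"g": 1.0},
                              noise_sd=0.5, master_seed=3)
        configs, _, _ = simulate_population(spec)
        from craniomorph.geometry import gpa
        consensus = gpa([c.coords for c in configs]).consensus * 500.0
        target_full = configs[0].with_coords(consensus)
        damaged = delete_left(target_full, n=15)
        res = estimate_missing_from_reference(
            damaged, [target_full.with_coords(consensus)])
        fill = ~damaged.present
        np.testing.assert_allclose(res.completed.coords[fill],
                                   consensus[fill], atol=1e-6)

    def test_single_specimen_exact(self, template_pack):
        tpl, _, _ = template_pack
        damaged = delete_left(tpl, n=12)
        res = estimate_missing_from_reference(damaged, [tpl])
        fill = ~damaged.present
        np.testing.assert_allclose(res.completed.coords[fill],
                                   tpl.coords[fill], atol=1e-6)

    @pytest.mark.parametrize("sigma", [1.0, 0.5, 0.1])
    def test_loo_recovery_below_noise(self, sigma):
        spec = SimulationSpec(n_specimens={"g": 30}, group_effects={"g": 0.0},
                              noise_sd=sigma, master_seed=17)
        configs, _, _ = simulate_population(spec)
        errs = []
        for k in range(6):
            target = configs[k]
            others = [c for i, c in enumerate(configs) if i != k]
            damaged = delete_left(target, n=12)
            res = estimate_missing_from_reference(damaged, others)
            fill = ~damaged.present
            errs.append(np.sqrt(
                ((res.completed.coords[fill] - target.coords[fill]) ** 2
                 ).sum(1).mean()))
        assert np.mean(errs) < 3 * sigma

    def test_rmse_decreases_with_noise(self):
        means = []
        for sigma in (1.0, 0.5, 0.1):
            spec = SimulationSpec(n_specimens={"g": 30},
                                  group_effects={"g": 0.0},
                                  noise_sd=sigma, master_seed=17)
            configs, _, _ = simulate_population(spec)
            damaged = delete_left(configs[0], n=12)
            res = estimate_missing_from_reference(damaged, configs[1:])
            fill = ~damaged.present
            means.append(np.sqrt(
                ((res.completed.coords[fill] - configs[0].coords[fill]) ** 2
                 ).sum(1).mean()))
        assert means[0] > means[1] > means[2]

    def test_similarity_equivariance(self, rng):
        spec = SimulationSpec(n_specimens={"g": 8}, group_effects={"g": 0.0},
                              noise_sd=0.5, master_seed=5)
        configs, _, _ = simulate_population(spec)
        damaged = delete_left(configs[0], n=10)
        res = estimate_missing_from_reference(damaged, configs[1:])
        xf = random_similarity(rng)
        damaged_t = damaged.with_coords(
            np.where(damaged.present[:, None], xf.apply(damaged.coords),
                     np.nan))
        refs_t = [c.with_coords(xf.apply(c.coords)) for c in configs[1:]]
        res_t = estimate_missing_from_reference(damaged_t, refs_t)
        np.testing.assert_allclose(res_t.completed.coords,
                                   xf.apply(res.completed.coords), atol=1e-6)

    def test_empty_subsample(self, template_pack):
        tpl, _, _ = template_pack
        with pytest.raises(ReconstructionError):
            estimate_missing_from_reference(delete_left(tpl, 5), [])


class TestSelectClosest:
    def test_exact_copy_ranked_first(self, rng):
        spec = SimulationSpec(n_specimens={"g": 10}, group_effects={"g": 1.0},
                              noise_sd=1.0, master_seed=2)
        configs, _, _ = simulate_population(spec)
        sample = ReferenceSample(configs)
        target = configs[3].with_coords(
            random_similarity(rng).apply(configs[3].coords))
        ranked = select_closest(target, sample, k=3)
        assert ranked[0][0] == configs[3].specimen_id
        assert ranked[0][1] == pytest.approx(0.0, abs=1e-8)

    def test_k_equals_sample_size(self):
        spec = SimulationSpec(n_specimens={"g": 6}, group_effects={"g": 1.0},
                              noise_sd=1.0, master_seed=2)
        configs, _, _ = simulate_population(spec)
        sample = ReferenceSample(configs)
        ranked = select_closest(configs[0], sample, k=6)
        assert sorted(sid for sid, _ in ranked) == \
               sorted(c.specimen_id for c in configs)

    def test_ranking_matches_deformation_magnitude(self, template_pack):
        tpl, _, _ = template_pack
        from craniomorph.tps import tps_fit, tps_apply
        rng = np.random.default_rng(8)
        controls = rng.uniform(-80, 80, size=(6, 3))
        disp = rng.normal(size=(6, 3))
        disp /= np.sqrt((disp ** 2).sum(1).mean())
        members = []
        for k, mag in enumerate([0.5, 1.0, 2.0, 4.0, 8.0]):
            model = tps_fit(controls, controls + mag * disp)
            members.append(tpl.with_coords(tps_apply(model, tpl.coords)))
            members[-1].specimen_id = f"def_{k}"
        sample = ReferenceSample(members)
        ranked = select_closest(tpl, sample, k=5)
        assert [sid for sid, _ in ranked] == [f"def_{k}" for k in range(5)]

    def test_k_too_large(self, template_pack):
        tpl, _, _ = template_pack
        sample = ReferenceSample([tpl.copy()])
        with pytest.raises(ValueError):
            select_closest(tpl, sample, k=2)


class TestEnsemble:
    def test_seven_subsamples(self):
        scen = default_reconstruction_scenario(seed=2)
        results = reconstruct_ensemble(scen["target"], scen["reference"],
                                       scen["subsample_specs"],
                                       scen["pairing"])
        assert len(results) == 7
        assert [r.subsample_name for r in results] == [
            "all", "recent", "recent_males", "recent_females",
            "closest_10", "closest_1", "fossil"]
        for r in results:
            assert r.completed.is_complete
            provs = set(r.provenance.values())
            assert provs <= {Provenance.ORIGINAL, Provenance.MIRRORED,
                             Provenance.REFERENCE_ESTIMATED}

    def test_bitwise_determinism(self):
        scen = default_reconstruction_scenario(seed=2)
        specs = scen["subsample_specs"] + [scen["subsample_specs"][0]]
        results = reconstruct_ensemble(scen["target"], scen["reference"],
                                       specs, scen["pairing"])
        np.testing.assert_array_equal(results[0].completed.coords,
                                      results[-1].completed.coords)

    def test_unresolvable_spec(self):
        scen = default_reconstruction_scenario(seed=2)
        bad = [SubsampleSpec("closest_40", "closest", k=40)]
        with pytest.raises(ValueError):
            reconstruct_ensemble(scen["target"], scen["reference"], bad,
                                 scen["pairing"])


class TestMirrorAcrossMidplane:
    def test_right_block_fills_left(self, template_pack):
        tpl, pairing, _ = template_pack
        damaged = delete_left(tpl)
        right_ids = [d.id for d in tpl.template if d.side is Side.RIGHT]
        res = mirror_across_midplane(right_ids, damaged, pairing)
        left_idx = [i for i, d in enumerate(tpl.template)
                    if d.side is Side.LEFT]
        np.testing.assert_allclose(res.completed.coords[left_idx],
                                   tpl.coords[left_idx], atol=1e-8)

    def test_conflict_without_overwrite(self, template_pack):
        tpl, pairing, _ = template_pack
        right_ids = [d.id for d in tpl.template if d.side is Side.RIGHT]
        with pytest.raises(ReconstructionError, match="already present"):
            mirror_across_midplane(right_ids, tpl, pairing)
        res = mirror_across_midplane(right_ids, tpl, pairing, overwrite=True)
        assert res.completed.is_complete


class TestWarpDonorMesh:
    def test_identity_and_affine(self, template_pack, rng):
        import trimesh
        tpl, _, _ = template_pack
        mesh = trimesh.creation.icosphere(subdivisions=1, radius=60.0)
        same = warp_donor_mesh(mesh, tpl, tpl)
        np.testing.assert_allclose(same.vertices, mesh.vertices, atol=1e-6)
        A = np.eye(3) + 0.05 * rng.normal(size=(3, 3))
        b = rng.normal(size=3)
        target = tpl.with_coords(tpl.coords @ A.T + b)
        warped = warp_donor_mesh(mesh, tpl, target)
        np.testing.assert_allclose(
            warped.vertices, np.asarray(mesh.vertices) @ A.T + b, atol=1e-6)
        np.testing.assert_array_equal(warped.faces, mesh.faces)

    def test_landmark_vertices_interpolate(self, template_pack, rng):
        import trimesh
        tpl, _, _ = template_pack
        verts = np.vstack([tpl.coords,
                           tpl.coords.mean(0) + rng.normal(size=(3, 3)) * 30])
        n = len(tpl.coords)
        faces = [[i, i + 1, n] for i in range(0, n - 1, 2)]
        mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
        target = tpl.with_coords(
            tpl.coords + rng.normal(scale=1.5, size=tpl.coords.shape))
        warped = warp_donor_mesh(mesh, tpl, target)
        np.testing.assert_allclose(warped.vertices[:n], target.coords,
                                   atol=1e-7)
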