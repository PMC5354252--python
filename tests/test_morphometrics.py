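"""Landmark distances, Procrustes superimposition, symmetrization, mesh
areas, melanin index and observer reliability."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from qstfst import morphometrics as mm


def _template_frame():
    from qstfst.synthetic_data import TEMPLATE_LANDMARKS

    return pd.DataFrame(
        {lm: xyz for lm, xyz in TEMPLATE_LANDMARKS.items()},
        index=["x", "y", "z"],
    ).T.rename_axis("landmark")


class TestProcrustes:
    def _random_rigid(self, config, seed):
        rng = np.random.default_rng(seed)
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.normal(0, 10, 3)
        return config @ R.T + t

    def test_rigid_copies_align_to_machine_precision(self):
        base = _template_frame()[["x", "y", "z"]].to_numpy()
        moved = self._random_rigid(base, 1)
        aligned, _ = mm.procrustes_align(np.stack([base, moved]))
        rms = np.sqrt(((aligned[0] - aligned[1]) ** 2).mean())
        assert rms < 1e-8

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        base = _template_frame()[["x", "y", "z"]].to_numpy()
        configs = np.stack(
            [self._random_rigid(base + rng.normal(0, 0.5, base.shape), s)
             for s in range(4)]
        )
        aligned, _ = mm.procrustes_align(configs)
        again, _ = mm.procrustes_align(aligned)
        assert np.abs(aligned - again).max() < 1e-6

    def test_consensus_approaches_template(self):
        """The consensus of N noisy copies converges to the template shape
        as N grows (law of large numbers, after re-alignment)."""
        base = _template_frame()[["x", "y", "z"]].to_numpy()
        base = base - base.mean(axis=0)
        errs = []
        for n in (8, 128):
            rng = np.random.default_rng(42)
            configs = np.stack(
                [base + rng.normal(0, 1.0, base.shape) for _ in range(n)]
            )
            _, consensus = mm.procrustes_align(configs)
            aligned, _ = mm.procrustes_align(np.stack([base, consensus]))
            errs.append(np.abs(aligned[0] - aligned[1]).max())
        assert errs[1] < errs[0]

    def test_scale_preserved_by_default(self):
        base = _template_frame()[["x", "y", "z"]].to_numpy()
        moved = self._random_rigid(base * 1.0, 3)
        aligned, _ = mm.procrustes_align(np.stack([base, moved]))
        d_before = np.linalg.norm(base[0] - base[1])
        d_after = np.linalg.norm(aligned[0][0] - aligned[0][1])
        assert d_after == pytest.approx(d_before, rel=1e-10)

    def test_degenerate_configuration_rejected(self):
        flat = np.zeros((2, 7, 3))
        with pytest.raises(ValueError, match="degenerate"):
            mm.procrustes_align(flat)


class TestSymmetrize:
    def test_symmetric_input_is_fixed_point(self):
        lm = _template_frame()
        refl = mm.reflect(lm)
        out = mm.symmetrize(lm[["x", "y", "z"]].to_numpy(),
                            refl[["x", "y", "z"]].to_numpy())
        np.testing.assert_allclose(out, lm[["x", "y", "z"]].to_numpy(),
                                   atol=1e-12)

    def test_asymmetry_split_in_half(self):
        """al_l displaced 2 mm laterally: the symmetrized configuration is
        off by 1 mm on each side."""
        lm = _template_frame()
        lm.loc["al_l", "x"] -= 2.0
        refl = mm.reflect(lm)
        out = mm.symmetrize(lm[["x", "y", "z"]].to_numpy(),
                            refl[["x", "y", "z"]].to_numpy())
        out = pd.DataFrame(out, index=lm.index, columns=["x", "y", "z"])
        assert out.loc["al_l", "x"] == pytest.approx(-18.0)  # template -17 -2+1
        assert out.loc["al_r", "x"] == pytest.approx(18.0)

    def test_midline_lands_on_symmetry_plane(self):
        rng = np.random.default_rng(4)
        lm = _template_frame()
        lm[["x", "y", "z"]] += rng.normal(0, 0.5, (7, 3))
        refl = mm.reflect(lm)
        out = pd.DataFrame(
            mm.symmetrize(lm[["x", "y", "z"]].to_numpy(),
                          refl[["x", "y", "z"]].to_numpy()),
            index=lm.index, columns=["x", "y", "z"],
        )
        for midline in mm.MIDLINE_LANDMARKS:
            assert abs(out.loc[midline, "x"]) < 1e-8

    def test_non_involution_pairing_rejected(self):
        a = np.zeros((3, 3))
        with pytest.raises(ValueError, match="involution"):
            mm.symmetrize(a, a, pairing={0: 1, 1: 2, 2: 0})


class TestDistances:
    def test_three_four_five_triangle(self):
        lm = {k: (0.0, 0, 0) for k in mm.LANDMARKS}
        lm["al_l"] = (0.0, 0, 0)
        lm["al_r"] = (3.0, 4, 0)
        lm["n"] = (1.0, 1, 1)
        d = mm.landmark_distances(lm)
        assert d["nares_width"] == pytest.approx(5.0)
        assert d["alar_base_width"] == 0.0  # coincident pair

    def test_missing_landmark_named_in_error(self):
        lm = {k: (0.0, 0, 0) for k in mm.LANDMARKS if k != "prn"}
        with pytest.raises(ValueError, match="prn"):
            mm.landmark_distances(lm)

    def test_rigid_invariance(self):
        lm = _template_frame()
        d0 = mm.landmark_distances(lm)
        R = Rotation.from_euler("xyz", [20, -35, 7], degrees=True).as_matrix()
        moved = lm.copy()
        moved[["x", "y", "z"]] = lm[["x", "y", "z"]].to_numpy() @ R.T + [5, -3, 2]
        d1 = mm.landmark_distances(moved)
        for k in d0:
            assert d1[k] == pytest.approx(d0[k], rel=1e-12)


class TestAreas:
    def test_right_triangle_and_unit_square(self):
        verts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]])
        assert mm.region_area(verts, np.array([[0, 1, 2]])) == pytest.approx(0.5)
        assert mm.region_area(
            verts, np.array([[0, 1, 2], [1, 3, 2]])
        ) == pytest.approx(1.0)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(5)
        verts = rng.normal(0, 10, (20, 3))
        faces = rng.integers(0, 20, (30, 3))
        a0 = mm.region_area(verts, faces)
        R = Rotation.random(rng=rng).as_matrix()
        a1 = mm.region_area(verts @ R.T, faces)
        assert abs(a1 - a0) < 1e-10

    def test_region_mask_restricts_triangles(self):
        verts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]])
        faces = np.array([[0, 1, 2], [1, 3, 2]])
        assert mm.region_area(verts, faces, region=[0, 1, 2]) == pytest.approx(0.5)

    def test_empty_region_rejected(self):
        verts = np.eye(3)
        with pytest.raises(ValueError, match="region"):
            mm.region_area(verts, np.array([[0, 1, 2]]), region=[0])

    def test_trimesh_agrees_on_random_surface(self):
        """Cross-check against trimesh's area on a closed icosphere."""
        import trimesh

        mesh = trimesh.creation.icosphere(subdivisions=2, radius=3.0)
        ours = mm.region_area(mesh.vertices, mesh.faces)
        assert ours == pytest.approx(mesh.area, rel=1e-10)


class TestMelaninIndex:
    def test_known_values(self):
        assert mm.melanin_index(1.0) == pytest.approx(0.0)
        assert mm.melanin_index(0.5) == pytest.approx(30.103, abs=1e-3)

    def test_strictly_decreasing_in_reflectance(self):
        r = np.linspace(0.05, 1.0, 50)
        mi = mm.melanin_index(r)
        assert np.all(np.diff(mi) < 0)

    def test_percent_scale_autodetected_with_warning(self):
        with pytest.warns(UserWarning, match="percent"):
            assert mm.melanin_index(50.0) == pytest.approx(30.103, abs=1e-3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mm.melanin_index(0.0)
        with pytest.raises(ValueError):
            mm.melanin_index(150.0)

    def test_inverse_transform(self):
        assert mm.inverse_melanin_index(40.0) == pytest.approx(0.025)


class TestICC:
    def _replicated(self, sd_subj, sd_err, n_subj=200, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_subj):
            mu = rng.normal(0, sd_subj)
            for obs in ("o1", "o2"):
                for rep in range(3):
                    rows.append(
                        {
                            "subject": f"s{i}",
                            "observer": obs,
                            "replicate": rep,
                            "d": 10 + mu + rng.normal(0, sd_err),
                        }
                    )
        return pd.DataFrame(rows)

    def test_zero_noise_gives_one(self):
        df = self._replicated(sd_subj=2.0, sd_err=0.0)
        assert mm.icc(df, "d").icc == pytest.approx(1.0)

    def test_nine_to_one_variance_ratio(self):
        """Subject:error variance 9:1 puts the ICC at 0.9."""
        res = mm.icc(self._replicated(sd_subj=3.0, sd_err=1.0), "d")
        assert res.icc == pytest.approx(0.9, abs=0.03)

    def test_observer_shift_does_not_deflate_icc(self):
        """Observer is a fixed effect: a constant between-observer offset
        must not count as error variance."""
        df = self._replicated(sd_subj=3.0, sd_err=1.0, seed=1)
        df.loc[df["observer"] == "o2", "d"] += 5.0
        res = mm.icc(df, "d")
        assert res.icc == pytest.approx(0.9, abs=0.03)

    def test_reports_observer_sd_quantiles(self):
        res = mm.icc(self._replicated(3.0, 1.0, n_subj=50), "d")
        q = res.observer_sd_quantiles
        assert set(q["observer"]) == {"o1", "o2"}
        assert (q["upper_97.5%"] >= q["lower_2.5%"]).all()

    def test_single_subject_rejected(self):
        df = self._replicated(1.0, 1.0, n_subj=1)
        with pytest.raises(ValueError, match="single subject"):
            mm.icc(df, "d")

    def test_icc_bounded(self):
        res = mm.icc(self._replicated(0.0, 1.0, n_subj=60, seed=2), "d")
        assert 0.0 <= res.icc <= 1.0


class TestReplicateAveraging:
    def test_observer_then_replicate_mean_order(self):
        """Distances average within observer replicates first, then across
        observers: an observer with more replicates must not dominate."""
        from qstfst.synthetic_data import TEMPLATE_LANDMARKS

        rows = []
        # observer o1: two replicates with nares widths 34 and 34
        # observer o2: one replicate with al_r shifted (+2 -> width 36)
        for obs, reps, shift in [("o1", [0, 0], 0.0), ("o2", [0], 2.0)]:
            for rep, _ in enumerate(reps):
                for lm, xyz in TEMPLATE_LANDMARKS.items():
                    x, y, z = xyz
                    if lm == "al_r":
                        x += shift
                    rows.append(
                        {"id": "p1", "observer": obs, "replicate": rep,
                         "landmark": lm, "x": x, "y": y, "z": z}
                    )
        out = mm.replicate_mean_traits(pd.DataFrame(rows))
        assert out.loc[0, "nares_width"] == pytest.approx((34 + 36) / 2)

    def test_incomplete_replicate_excluded(self):
        from qstfst.synthetic_data import TEMPLATE_LANDMARKS

        rows = []
        for lm, xyz in TEMPLATE_LANDMARKS.items():
            rows.append({"id": "p1", "observer": "o1", "replicate": 0,
                         "landmark": lm, "x": xyz[0], "y": xyz[1], "z": xyz[2]})
        rows += rows[:-1]  # second replicate missing one landmark -> dropped
        df = pd.DataFrame(rows)
        df.loc[7:, "replicate"] = 1
        with pytest.warns(UserWarning, match="incomplete"):
            out = mm.replicate_mean_traits(df)
        assert len(out) == 1
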