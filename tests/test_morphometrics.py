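"""TPS I/O and Generalized Procrustes superimposition."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import orthogonal_procrustes

from finstripe import (LabeledFeatureTable, LandmarkSet, combine, gpa,
                       procrustes_coordinates, read_tps, write_tps)
from finstripe.errors import LabelMismatchError, TPSFormatError
from finstripe.morphometrics import N_LANDMARKS, procrustes_coordinate_names


def random_config(rng, spread=10.0):
    return LandmarkSet(coords=rng.normal(scale=spread, size=(N_LANDMARKS, 2)),
                       specimen_id=f"s{rng.integers(1e6)}")


def similarity_transform(coords, angle, scale, shift):
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    return scale * coords @ rot.T + shift


class TestTPS:
    def test_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(0)
        sets = [random_config(rng) for _ in range(3)]
        path = tmp_path / "landmarks.tps"
        write_tps(sets, path)
        loaded = read_tps(path)
        assert [s.specimen_id for s in loaded] == [s.specimen_id for s in sets]
        for a, b in zip(loaded, sets):
            np.testing.assert_allclose(a.coords, b.coords, atol=1e-6)

    def test_wrong_landmark_count_rejected(self, tmp_path):
        path = tmp_path / "bad.tps"
        lines = ["LM=16"] + ["%d %d" % (i, i) for i in range(16)] + ["ID=x"]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(TPSFormatError, match="expected 17 landmarks"):
            read_tps(path)

    def test_malformed_coordinate_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.tps"
        lines = ["LM=17"] + ["%d %d" % (i, i) for i in range(16)] + ["oops"]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(TPSFormatError, match="line 18"):
            read_tps(path)

    def test_flip_y_converts_raster_to_cartesian(self, tmp_path):
        rng = np.random.default_rng(1)
        sets = [random_config(rng)]
        path = tmp_path / "landmarks.tps"
        write_tps(sets, path)
        flipped = read_tps(path, flip_y=100.0)
        np.testing.assert_allclose(flipped[0].coords[:, 1],
                                   100.0 - sets[0].coords[:, 1], atol=1e-6)


class TestGPA:
    def test_identical_configurations_align_exactly(self):
        rng = np.random.default_rng(2)
        base = random_config(rng)
        result = gpa([LandmarkSet(base.coords.copy(), f"s{i}")
                      for i in range(4)])
        for aligned in result.aligned:
            np.testing.assert_allclose(aligned, result.aligned[0], atol=1e-12)

    def test_similarity_transform_removed(self):
        rng = np.random.default_rng(3)
        base = random_config(rng)
        moved = LandmarkSet(similarity_transform(base.coords, angle=0.9,
                                                 scale=2.3, shift=(40, -17)),
                            "moved")
        result = gpa([base, moved])
        diff = np.sqrt(((result.aligned[0] - result.aligned[1]) ** 2).sum())
        assert diff < 1e-8

    def test_unit_centroid_size_and_centered_consensus(self):
        rng = np.random.default_rng(4)
        result = gpa([random_config(rng) for _ in range(6)])
        for aligned in result.aligned:
            np.testing.assert_allclose(aligned.mean(axis=0), 0.0, atol=1e-8)
            assert np.sqrt((aligned ** 2).sum()) == pytest.approx(1.0, abs=1e-8)
        np.testing.assert_allclose(result.consensus.mean(axis=0), 0.0,
                                   atol=1e-8)
        np.testing.assert_allclose(result.consensus,
                                   result.aligned.mean(axis=0), atol=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_two_configuration_rotation_matches_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        a, b = random_config(rng), random_config(rng)
        result = gpa([a, b])

        def unit(coords):
            c = coords - coords.mean(axis=0)
            return c / np.sqrt((c ** 2).sum())

        ua, ub = unit(a.coords), unit(b.coords)
        # independent closed-form oracle for the optimal rotation of b onto a
        rot, _ = orthogonal_procrustes(ub, ua)
        if np.linalg.det(rot) < 0:  # rotation-only convention
            u, s, vt = np.linalg.svd(ub.T @ ua)
            u[:, -1] *= -1
            rot = u @ vt
        oracle_resid = np.sqrt(((ub @ rot - ua) ** 2).sum())
        gpa_resid = np.sqrt(((result.aligned[1] - result.aligned[0]) ** 2).sum())
        assert gpa_resid == pytest.approx(oracle_resid, abs=1e-6)

    def test_reflection_not_absorbed(self):
        rng = np.random.default_rng(9)
        base = random_config(rng)
        mirrored = LandmarkSet(base.coords * np.array([-1.0, 1.0]), "mirror")
        result = gpa([base, mirrored])
        diff = np.sqrt(((result.aligned[0] - result.aligned[1]) ** 2).sum())
        assert diff > 1e-3

    def test_degenerate_configuration_rejected(self):
        flat = LandmarkSet(np.ones((N_LANDMARKS, 2)), "flat")
        rng = np.random.default_rng(10)
        with pytest.warns(UserWarning, match="coincident"):
            flat = LandmarkSet(np.ones((N_LANDMARKS, 2)), "flat")
        with pytest.raises(ValueError, match="degenerate"):
            gpa([flat, random_config(rng)])


class TestCoordinatesAndCombine:
    def test_17_landmarks_yield_34_named_columns(self):
        rng = np.random.default_rng(5)
        result = gpa([random_config(rng) for _ in range(3)])
        coords = procrustes_coordinates(result)
        assert coords.shape == (3, 34)
        assert list(coords.columns) == procrustes_coordinate_names()
        assert "ProcCoord_5y" in coords.columns

    def test_row_reshapes_back_to_aligned_configuration(self):
        rng = np.random.default_rng(6)
        result = gpa([random_config(rng) for _ in range(3)])
        coords = procrustes_coordinates(result)
        np.testing.assert_allclose(
            coords.iloc[1].to_numpy().reshape(N_LANDMARKS, 2),
            result.aligned[1])

    def test_combine_appends_34_shape_variables(self):
        rng = np.random.default_rng(7)
        ids = ["s1", "s2", "s3"]
        features = LabeledFeatureTable(
            pd.DataFrame(rng.normal(size=(3, 48)), index=ids,
                         columns=[f"f{i}" for i in range(48)]),
            pd.Series(["a", "b", "a"], index=ids))
        shapes = pd.DataFrame(rng.normal(size=(3, 34)), index=ids,
                              columns=procrustes_coordinate_names())
        combined = combine(features, shapes)
        assert combined.p == 82

    def test_combine_rejects_permuted_ids(self):
        rng = np.random.default_rng(8)
        ids = ["s1", "s2", "s3"]
        features = LabeledFeatureTable(
            pd.DataFrame(rng.normal(size=(3, 2)), index=ids),
            pd.Series(["a", "b", "a"], index=ids))
        shapes = pd.DataFrame(rng.normal(size=(3, 34)),
                              index=["s2", "s1", "s3"],
                              columns=procrustes_coordinate_names())
        with pytest.raises(LabelMismatchError, match="mismatch"):
            combine(features, shapes)

    def test_combine_passes_through_empty_shapes_with_warning(self):
        rng = np.random.default_rng(9)
        ids = ["s1", "s2"]
        features = LabeledFeatureTable(
            pd.DataFrame(rng.normal(size=(2, 3)), index=ids),
            pd.Series(["a", "b"], index=ids))
        with pytest.warns(UserWarning, match="empty shape"):
            out = combine(features, pd.DataFrame(index=ids))
        assert out.p == 3
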