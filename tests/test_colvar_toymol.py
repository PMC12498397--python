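"""CV measurement, chelate dihedral, frame round-trips, subsampling."""

import numpy as np
import pandas as pd
import pytest

from photomech import (RoleMap, ToyComplexTemplate, build_frame, build_frames,
                       chelate_dihedral, fold_theta, measure_cv,
                       measure_series, quasi_uniform_subsample)


@pytest.fixture()
def template():
    return ToyComplexTemplate()


def _random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


class TestMeasureCV:
    def test_single_oxygen_distance(self, template, rng):
        frame, roles = build_frame(template, 2.3, 3.0, 60.0, 0.0, rng)
        cv = measure_cv(frame, roles)
        assert cv.d_RuOmin == pytest.approx(3.0, abs=1e-9)

    def test_argmin_selects_the_nearest_oxygen(self, rng):
        # Ru at origin, S on z, two oxygens at 2.8 and 3.5 Å
        frame = np.array([
            [0.0, 0.0, 0.0], [0.0, 0.0, 2.3],
            [2.05, 0, 0], [3.0, 0, 0.7], [0, 0, -2.05], [1.2, 0, -2.7],
            [2.8, 0.0, 0.0],                 # O at 2.8, alpha 90°
            [0.0, 0.0, -3.5],                # O at 3.5
        ])
        roles = RoleMap(Ru=0, S=1, N_C=2, C_C=3, N_T=4, C_T=5,
                        solvent_O=(6, 7))
        cv = measure_cv(frame, roles)
        assert cv.d_RuOmin == pytest.approx(2.8)
        assert cv.alpha == pytest.approx(90.0)

    def test_matches_exhaustive_search_over_oxygens(self, template, rng):
        for _ in range(100):
            d_s = rng.uniform(2.1, 5.5)
            d_o = rng.uniform(2.0, 5.0)
            frame, roles = build_frame(template, d_s, d_o,
                                       rng.uniform(5, 175), 0.0, rng)
            cv = measure_cv(frame, roles)
            ru = frame[roles.Ru]
            brute = min(np.linalg.norm(frame[i] - ru)
                        for i in roles.solvent_O)
            assert cv.d_RuOmin == pytest.approx(brute, abs=1e-12)

    def test_missing_solvent_raises(self, rng):
        frame = np.array([[0.0, 0, 0], [0, 0, 2.3], [2.05, 0, 0],
                          [3.0, 0, 0.7], [0, 0, -2.05], [1.2, 0, -2.7]])
        roles = RoleMap(Ru=0, S=1, N_C=2, C_C=3, N_T=4, C_T=5)
        with pytest.raises(ValueError, match="solvent"):
            measure_cv(frame, roles)

    def test_rigid_body_invariance(self, template, rng):
        frame, roles = build_frame(template, 2.6, 3.2, 75.0, 25.0, rng)
        cv0 = measure_cv(frame, roles)
        R = _random_rotation(rng)
        moved = frame @ R.T + np.array([3.0, -7.0, 11.0])
        cv1 = measure_cv(moved, roles)
        for attr in ("d_RuS", "d_RuOmin", "alpha", "theta"):
            assert getattr(cv1, attr) == pytest.approx(
                getattr(cv0, attr), abs=1e-9)


class TestChelateDihedral:
    def test_coplanar_chelate_gives_zero(self, template, rng):
        frame, roles = build_frame(template, 2.3, 4.0, 60.0, 0.0, rng)
        assert fold_theta(chelate_dihedral(frame, roles)) == \
            pytest.approx(0.0, abs=1e-9)

    def test_perpendicular_half_planes_give_ninety(self, template, rng):
        frame, roles = build_frame(template, 2.3, 4.0, 60.0, 90.0, rng)
        assert fold_theta(chelate_dihedral(frame, roles)) == \
            pytest.approx(90.0, abs=1e-9)

    def test_matches_independent_normal_vector_oracle(self, rng):
        for _ in range(50):
            frame = rng.normal(scale=2.0, size=(6, 3))
            roles = RoleMap(Ru=0, S=1, N_C=2, C_C=3, N_T=4, C_T=5,
                            solvent_O=())
            ru = frame[0]
            n1 = np.cross(frame[2] - ru, frame[3] - ru)
            n2 = np.cross(frame[4] - ru, frame[5] - ru)
            if min(np.linalg.norm(n1), np.linalg.norm(n2)) < 1e-6:
                continue
            cosv = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
            expected = np.degrees(np.arccos(np.clip(cosv, -1, 1)))
            got = chelate_dihedral(frame, roles)
            assert abs(got) == pytest.approx(expected, abs=1e-6)

    def test_collinear_plane_raises(self):
        frame = np.zeros((6, 3))
        frame[1] = [0, 0, 2.3]
        frame[2] = [1.0, 0, 0]
        frame[3] = [2.0, 0, 0]        # Ru, N_C, C_C collinear
        frame[4] = [0, 0, -2.0]
        frame[5] = [1.0, 0, -2.6]
        roles = RoleMap(Ru=0, S=1, N_C=2, C_C=3, N_T=4, C_T=5)
        with pytest.raises(ValueError, match="collinear"):
            chelate_dihedral(frame, roles)


class TestBuildFrames:
    def test_round_trip_is_exact(self, template, rng):
        frame, roles = build_frame(template, 2.3, 4.0, 60.0, 0.0, rng)
        cv = measure_cv(frame, roles)
        assert cv.d_RuS == pytest.approx(2.3, abs=1e-9)
        assert cv.d_RuOmin == pytest.approx(4.0, abs=1e-9)
        assert cv.alpha == pytest.approx(60.0, abs=1e-6)

    def test_thousand_random_tuples_round_trip(self, template, rng):
        """Max round-trip error < 1e-5 against re-measurement."""
        worst = 0.0
        for _ in range(1000):
            d_s = rng.uniform(2.0, 5.9)
            d_o = rng.uniform(2.0, 5.5)
            alpha = rng.uniform(1.0, 179.0)
            theta = rng.uniform(-170.0, 170.0)
            frame, roles = build_frame(template, d_s, d_o, alpha, theta, rng)
            cv = measure_cv(frame, roles)
            worst = max(worst, abs(cv.d_RuS - d_s), abs(cv.d_RuOmin - d_o),
                        abs(cv.alpha - alpha) / 1e3,
                        abs(fold_theta(cv.theta) - fold_theta(theta)) / 1e3)
        assert worst < 1e-5

    def test_decoys_never_shadow_the_placed_oxygen(self, template, rng):
        for _ in range(50):
            d_o = rng.uniform(2.0, 5.0)
            frame, roles = build_frame(template, 2.5, d_o, 70.0, 0.0, rng)
            ru = frame[roles.Ru]
            dists = sorted(np.linalg.norm(frame[i] - ru)
                           for i in roles.solvent_O)
            assert dists[0] == pytest.approx(d_o, abs=1e-9)
            assert dists[1] >= d_o + template.decoy_margin - 1e-9

    def test_unrealizable_tuple_reports_row(self, template):
        path = pd.DataFrame({"d_RuS": [2.3, -1.0], "d_RuOmin": [3.0, 3.0],
                             "alpha": [60.0, 60.0]})
        with pytest.raises(ValueError, match="row 1"):
            build_frames(template, path)

    def test_series_round_trip_through_measure_series(self, template):
        path = pd.DataFrame({"d_RuS": [2.3, 3.1, 4.2],
                             "d_RuOmin": [4.0, 3.1, 2.4],
                             "alpha": [60.0, 110.0, 95.0]})
        theta = np.array([10.0, -35.0, 80.0])
        traj = build_frames(template, path, theta=theta, seed=3)
        series = measure_series(traj.frames, traj.roles)
        assert np.allclose(series["d_RuS"], path["d_RuS"], atol=1e-9)
        assert np.allclose(series["alpha"], path["alpha"], atol=1e-6)
        assert np.allclose(fold_theta(series["theta"]), fold_theta(theta),
                           atol=1e-4)


class TestQuasiUniformSubsample:
    def test_identity_when_n_out_equals_length(self):
        df = pd.DataFrame({"d_RuS": [1.0, 2.0, 3.0],
                           "d_RuOmin": [1.0, 2.0, 3.0]})
        out = quasi_uniform_subsample(df, 3)
        assert len(out) == 3

    def test_two_points_on_a_line_are_the_extremes(self):
        x = np.linspace(0, 1, 50)
        df = pd.DataFrame({"d_RuS": x, "d_RuOmin": np.zeros_like(x)})
        out = quasi_uniform_subsample(df, 2)
        assert set(out["d_RuS"]) == {0.0, 1.0}

    def test_beats_random_subsets_on_minimum_pairwise_distance(self, rng):
        pts = rng.uniform(size=(200, 2))
        df = pd.DataFrame({"d_RuS": pts[:, 0], "d_RuOmin": pts[:, 1]})
        sel = quasi_uniform_subsample(df, 10)
        p = sel[["d_RuS", "d_RuOmin"]].to_numpy()

        def min_pair(a):
            d = np.linalg.norm(a[:, None] - a[None], axis=-1)
            return d[np.triu_indices(len(a), 1)].min()

        ours = min_pair(p)
        best_random = max(
            min_pair(pts[rng.choice(200, size=10, replace=False)])
            for _ in range(1000))
        assert ours >= best_random

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            quasi_uniform_subsample(pd.DataFrame({"d_RuS": [],
                                                  "d_RuOmin": []}), 0)
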