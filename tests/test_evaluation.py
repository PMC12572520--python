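"""Evaluation: surface distances, localization rates, summaries, statistics."""

import numpy as np
import pytest
import trimesh

import ribalign as ra
from ribalign.errors import ConnectivityError, OffSurfaceError, ParameterError
from ribalign.evaluation import SurfaceDistance, records_from_csv, records_to_csv


@pytest.fixture(scope="module")
def sd_sphere(sphere_mesh_r100):
    return SurfaceDistance(sphere_mesh_r100, projection_tol=10.0)


def _unit(rng):
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


class TestSurfaceDistance:
    def test_coincident_points_have_zero_distance(self, sd_sphere):
        p = np.array([0.0, 0.0, 100.0])
        assert sd_sphere(p, p, "geodesic") == 0.0
        assert sd_sphere(p, p, "euclidean") == 0.0

    def test_antipodal_points_on_sphere(self, sd_sphere):
        a = np.array([0.0, 0.0, 100.0])
        b = np.array([0.0, 0.0, -100.0])
        geo = sd_sphere(a, b, "geodesic")
        euc = sd_sphere(a, b, "euclidean")
        assert abs(geo - np.pi * 100.0) / (np.pi * 100.0) < 0.05
        assert abs(euc - 200.0) / 200.0 < 0.02

    def test_geodesic_dominates_euclidean(self, sd_sphere):
        rng = np.random.default_rng(7)
        for _ in range(25):
            a, b = 100.0 * _unit(rng), 100.0 * _unit(rng)
            assert sd_sphere(a, b, "geodesic") >= sd_sphere(a, b, "euclidean") - 1e-9

    def test_pseudometric_symmetry_and_triangle_inequality(self, sd_sphere, sphere_mesh_r100):
        # All-pairs geodesics between 25 random surface points via
        # distance fields, then every ordered triple (13,800 > 1,000).
        rng = np.random.default_rng(42)
        pts = 100.0 * np.array([_unit(rng) for _ in range(25)])
        fields = [sd_sphere.geodesic_field(p) for p in pts]
        D = np.zeros((25, 25))
        for i, f in enumerate(fields):
            for j, p in enumerate(pts):
                D[i, j] = sd_sphere.geodesic_from_field(*f, p)
        np.testing.assert_allclose(D, D.T, atol=1e-6)
        for i in range(25):
            for j in range(25):
                for k in range(25):
                    assert D[i, k] <= D[i, j] + D[j, k] + 1e-6

    def test_field_evaluation_matches_pairwise_call(self, sd_sphere):
        rng = np.random.default_rng(3)
        a, b = 100.0 * _unit(rng), 100.0 * _unit(rng)
        f = sd_sphere.geodesic_field(a)
        assert sd_sphere.geodesic_from_field(*f, b) == pytest.approx(
            sd_sphere(a, b, "geodesic"), rel=1e-9
        )

    def test_refined_mesh_converges_toward_great_circle(self):
        a = np.array([0.0, 0.0, 100.0])
        b = np.array([0.0, 0.0, -100.0])
        errs = []
        for sub in (2, 3, 4):
            s = trimesh.creation.icosphere(subdivisions=sub, radius=100.0)
            sd = SurfaceDistance(ra.SurfaceMesh(np.asarray(s.vertices), np.asarray(s.faces)),
                                 projection_tol=20.0)
            errs.append(abs(sd(a, b, "geodesic") - np.pi * 100.0))
        assert errs[2] <= errs[0]

    def test_point_beyond_projection_tolerance_raises(self, sd_sphere):
        with pytest.raises(OffSurfaceError):
            sd_sphere(np.array([0.0, 0.0, 150.0]), np.array([0.0, 0.0, 100.0]))

    def test_disconnected_components_raise_in_geodesic_mode(self):
        s1 = trimesh.creation.icosphere(subdivisions=2, radius=10.0)
        s2 = trimesh.creation.icosphere(subdivisions=2, radius=10.0)
        s2.apply_translation([100.0, 0.0, 0.0])
        comb = trimesh.util.concatenate([s1, s2])
        sd = SurfaceDistance(ra.SurfaceMesh(np.asarray(comb.vertices), np.asarray(comb.faces)),
                             projection_tol=15.0)
        with pytest.raises(ConnectivityError):
            sd(np.array([0.0, 0.0, 10.0]), np.array([100.0, 0.0, 10.0]), "geodesic")


class TestLocalizationRate:
    @pytest.mark.parametrize("n_loc,n_tot,expected", [
        (22, 25, 88.0),     # clinical, mixed-reality system
        (14, 25, 56.0),     # clinical, ultrasound
        (22, 24, 91.67),    # preclinical
        (48, 48, 100.0),    # phantom protocol, 16 fractures x 3 positions
    ])
    def test_published_worked_examples(self, n_loc, n_tot, expected):
        assert ra.localization_rate(n_loc, n_tot) == expected

    def test_inconsistent_counts_raise(self):
        with pytest.raises(ParameterError):
            ra.localization_rate(26, 25)
        with pytest.raises(ParameterError):
            ra.localization_rate(0, 0)


class TestSummarizeAccuracy:
    @staticmethod
    def _rec(i, dist_mm, localized=True):
        return ra.LocalizationRecord(
            fracture_id=f"f{i}",
            true_point=np.zeros(3),
            localized_point=np.ones(3) if localized else None,
            distance_mm=dist_mm,
        )

    def test_hand_arithmetic_mean_and_sd(self):
        s = ra.summarize_accuracy([self._rec(i, d) for i, d in enumerate([10.0, 20.0, 30.0])])
        assert s.mean_cm == pytest.approx(2.0)
        assert s.sd_cm == pytest.approx(1.0)
        assert s.localization_rate == 100.0

    def test_single_record_flags_convention(self):
        s = ra.summarize_accuracy([self._rec(0, 12.0)])
        assert s.sd_cm == 0.0
        assert s.single_measurement

    def test_unmeasured_records_count_in_rate_but_not_mean(self):
        recs = [self._rec(0, 10.0), self._rec(1, None), self._rec(2, None, localized=False)]
        s = ra.summarize_accuracy(recs)
        assert s.n_measured == 1
        assert s.n_localized == 2
        assert s.localization_rate == pytest.approx(66.67)
        assert s.mean_cm == pytest.approx(1.0)

    def test_no_measured_records_yields_empty_marker(self):
        s = ra.summarize_accuracy([self._rec(0, None, localized=False)])
        assert s.empty
        assert s.mean_cm is None

    def test_csv_round_trip(self, tmp_path):
        recs = [self._rec(0, 10.0), self._rec(1, None, localized=False)]
        path = tmp_path / "records.csv"
        records_to_csv(recs, path)
        back = records_from_csv(path)
        assert back[0].distance_mm == pytest.approx(10.0)
        assert back[1].localized_point is None and back[1].distance_mm is None


def _welch_reference(a, b):
    """Independent Welch-formula implementation (textbook algebra + t CDF)."""
    from scipy.stats import t as tdist
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2.0 * tdist.sf(abs(t), df)
    return t, df, p


class TestCompareTwoMethods:
    def test_identical_groups_give_t0_p1(self):
        r = ra.compare_two_methods([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0
        assert r.p_value == 1.0
        assert not r.significant

    def test_fully_separated_groups_are_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 0.01, 4)
        b = 10.0 + rng.normal(0.0, 0.01, 4)
        assert ra.compare_two_methods(a, b).p_value < 0.001

    def test_matches_independent_welch_implementation(self):
        rng = np.random.default_rng(123)
        a = rng.normal(0.0, 1.0, 30)
        b = rng.normal(1.0, 1.0, 30)
        r = ra.compare_two_methods(a, b)
        t_ref, df_ref, p_ref = _welch_reference(a, b)
        assert r.statistic == pytest.approx(t_ref, abs=1e-6)
        assert r.df == pytest.approx(df_ref, abs=1e-6)
        assert r.p_value == pytest.approx(p_ref, abs=1e-6)

    def test_tiny_groups_rejected(self):
        with pytest.raises(ParameterError):
            ra.compare_two_methods([1.0], [1.0, 2.0])


class TestCompareGroupsAnova:
    def test_identical_groups_give_f0_and_unit_tukey(self):
        g = [1.0, 2.0, 3.0]
        r = ra.compare_groups_anova([g, g, g])
        assert r.f_statistic == 0.0
        assert r.p_value == 1.0
        assert all(t.p_adj == pytest.approx(1.0, abs=1e-9) for t in r.tukey)

    def test_single_shifted_group_detected(self):
        rng = np.random.default_rng(1)
        g1 = rng.normal(0, 1, 10)
        g2 = rng.normal(0, 1, 10)
        g3 = rng.normal(10, 1, 10)  # shifted by 10 SDs
        r = ra.compare_groups_anova([g1, g2, g3])
        assert r.p_value < 0.001
        flags = {(t.group_a, t.group_b): t.significant for t in r.tukey}
        assert not flags[(0, 1)]
        assert flags[(0, 2)] and flags[(1, 2)]

    def test_matches_statsmodels_tukey(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        rng = np.random.default_rng(5)
        groups = [rng.normal(m, 1.0, 12) for m in (0.0, 0.6, 1.5)]
        r = ra.compare_groups_anova(groups)
        data = np.concatenate(groups)
        labels = np.repeat([0, 1, 2], 12)
        sm = pairwise_tukeyhsd(data, labels)
        np.testing.assert_allclose(
            [t.p_adj for t in r.tukey], np.asarray(sm.pvalues, dtype=float), atol=1e-6
        )

    def test_matches_textbook_sum_of_squares_anova(self):
        from scipy.stats import f as fdist
        rng = np.random.default_rng(9)
        groups = [rng.normal(m, 1.0, 8) for m in (0, 0.5, 1.0, 2.0)]
        r = ra.compare_groups_anova(groups)
        # Independent reference: explicit between/within sums of squares.
        all_vals = np.concatenate(groups)
        grand = all_vals.mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        df_b, df_w = len(groups) - 1, len(all_vals) - len(groups)
        f_ref = (ss_between / df_b) / (ss_within / df_w)
        assert r.f_statistic == pytest.approx(f_ref, rel=1e-9)
        assert r.p_value == pytest.approx(float(fdist.sf(f_ref, df_b, df_w)), rel=1e-9)

    def test_too_few_groups_rejected(self):
        with pytest.raises(ParameterError):
            ra.compare_groups_anova([[1.0, 2.0], [3.0, 4.0]])
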