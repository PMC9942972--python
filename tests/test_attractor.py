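import numpy as np
import pandas as pd
import pytest
from scipy.stats import gaussian_kde

import attractorscape as ats
from attractorscape import attractor
from attractorscape.io import SampleTable, ValidationError
from attractorscape.pca import ProjectionTable


def samples_from(conditions, ages=None, stages=None, tissue="SIM"):
    n = len(conditions)
    ids = [f"S{i}" for i in range(n)]
    return SampleTable(
        pd.DataFrame(
            {
                "tissue_code": tissue,
                "condition": conditions,
                "age_years": ages if ages is not None else [np.nan] * n,
                "stage": pd.array(stages if stages is not None else [pd.NA] * n, dtype="string"),
            },
            index=pd.Index(ids, name="sample_id"),
        )
    )


class TestAgeSplit:
    def test_median_threshold_and_membership(self):
        s = samples_from(["normal", "normal", "tumor", "tumor"], ages=[50, 60, 70, 80])
        g = attractor.age_split(s)
        assert g.threshold == 65.0
        assert g.members["NY"] == ["S0", "S1"]
        assert g.members["TO"] == ["S2", "S3"]
        assert g.members["NO"] == [] and g.members["TY"] == []

    def test_equal_ages_all_old_degenerate(self):
        s = samples_from(["normal", "normal", "tumor", "tumor"], ages=[60] * 4)
        g = attractor.age_split(s)
        assert g.degenerate
        assert g.members["NO"] == ["S0", "S1"] and g.members["TO"] == ["S2", "S3"]
        assert "NY" in g.empty_groups

    def test_translation_property(self):
        ages = [45.0, 55.0, 65.0, 75.0, 50.0, 70.0]
        conds = ["normal"] * 3 + ["tumor"] * 3
        g1 = attractor.age_split(samples_from(conds, ages=ages))
        g2 = attractor.age_split(samples_from(conds, ages=[a + 7 for a in ages]))
        assert g2.threshold == g1.threshold + 7
        assert g2.members == g1.members

    def test_missing_ages_counted(self):
        s = samples_from(
            ["normal"] * 3 + ["tumor"] * 3, ages=[50, 70, np.nan, 50, 70, np.nan]
        )
        assert attractor.age_split(s).n_missing_age == 2

    def test_too_few_aged_samples_rejected(self):
        s = samples_from(["normal", "tumor", "tumor"], ages=[60, 50, 70])
        with pytest.raises(ValidationError):
            attractor.age_split(s)


class TestGroupDistribution:
    @staticmethod
    def matrix_and_groups(no_scale=1.0):
        genes = [f"G{i}" for i in range(4)]
        base = np.array([1.0, 2.0, 4.0, 8.0])
        data = {}
        for i, grp in enumerate(["NY", "NY", "NO", "NO", "TY", "TO"]):
            scale = no_scale if grp == "NO" else 1.0
            data[f"S{i}"] = base * scale
        m = ats.ExpressionMatrix(pd.DataFrame(data, index=genes))
        s = samples_from(
            ["normal"] * 4 + ["tumor"] * 2, ages=[50, 55, 70, 75, 50, 75]
        )
        return m, attractor.age_split(s)

    def test_identical_group_is_flat_one(self):
        m, groups = self.matrix_and_groups()
        curves = attractor.group_distribution(m, groups)
        assert np.allclose(curves["TY"], 1.0)
        assert np.allclose(curves["NY"], 1.0)

    def test_single_shifted_gene_counted(self):
        genes = ["G0", "G1", "G2"]
        cols = {
            "S0": [1.0, 1.0, 1.0],  # NY
            "S1": [1.0, 1.0, 1.0],  # NY
            "S2": [4.0, 1.0, 1.0],  # NO: one gene at 4x
            "S3": [4.0, 1.0, 1.0],  # NO
            "S4": [1.0, 1.0, 1.0],  # TY
            "S5": [1.0, 1.0, 1.0],  # TO
        }
        m = ats.ExpressionMatrix(pd.DataFrame(cols, index=genes))
        s = samples_from(["normal"] * 4 + ["tumor"] * 2, ages=[50, 55, 70, 75, 50, 75])
        curves = attractor.group_distribution(m, attractor.age_split(s))
        assert int((curves["NO"] > 2).sum()) == 1

    def test_counts_agree_with_tail_curve(self):
        m, groups = self.matrix_and_groups(no_scale=3.0)
        curves = attractor.group_distribution(m, groups)
        tc = ats.tail_curve(curves["NO"], "over", np.array([2.0]))
        assert tc.counts[0] == int((curves["NO"] > 2).sum())


class TestOverlapStatistic:
    def test_identical_curves(self):
        c = pd.Series({"a": 3.0, "b": 1.0})
        ov = attractor.overlap_statistic(c, c)
        assert ov.jaccard == 1.0 and ov.max_abs_log2_ratio == 0.0

    def test_disjoint_tails(self):
        a = pd.Series({"a": 3.0, "b": 1.0})
        b = pd.Series({"a": 1.0, "b": 3.0})
        assert attractor.overlap_statistic(a, b).jaccard == 0.0

    def test_empty_tails_identical(self):
        flat = pd.Series({"a": 1.0, "b": 1.0})
        assert attractor.overlap_statistic(flat, flat).jaccard == 1.0


class TestStageDensityDiff:
    @staticmethod
    def proj_and_samples(normal_pts, tumor_pts, stage="I"):
        n, t = len(normal_pts), len(tumor_pts)
        ids = [f"S{i}" for i in range(n + t)]
        proj = ProjectionTable(
            pd.DataFrame(
                np.vstack([normal_pts, tumor_pts]), index=ids, columns=["PC1", "PC2"]
            )
        )
        s = samples_from(
            ["normal"] * n + ["tumor"] * t, stages=[pd.NA] * n + [stage] * t
        )
        return proj, s

    def test_coincident_point_masses_cancel(self):
        proj, s = self.proj_and_samples([(0, 0)] * 3, [(0, 0)] * 3)
        field = attractor.stage_density_diff(proj, s, "I")
        assert np.allclose(field.field, 0.0, atol=1e-12)

    def test_sign_structure_of_separated_clouds(self, rng):
        normals = rng.normal(0, 0.5, size=(20, 2))
        tumors = rng.normal(0, 0.5, size=(20, 2)) + [10, 0]
        proj, s = self.proj_and_samples(normals, tumors)
        field = attractor.stage_density_diff(proj, s, "I")
        ix_n = np.argmin(np.abs(field.x - 0))
        ix_t = np.argmin(np.abs(field.x - 10))
        iy = np.argmin(np.abs(field.y - 0))
        assert field.field[iy, ix_n] > 0
        assert field.field[iy, ix_t] < 0

    def test_field_integrates_to_zero(self, rng):
        normals = rng.normal(0, 1, size=(25, 2))
        tumors = rng.normal(3, 1, size=(25, 2))
        proj, s = self.proj_and_samples(normals, tumors)
        field = attractor.stage_density_diff(proj, s, "I")
        assert abs(field.integral()) < 1e-3

    def test_sample_order_invariant(self, rng):
        normals = rng.normal(0, 1, size=(10, 2))
        tumors = rng.normal(4, 1, size=(10, 2))
        proj, s = self.proj_and_samples(normals, tumors)
        shuffled = ProjectionTable(proj.data.sample(frac=1.0, random_state=3))
        f1 = attractor.stage_density_diff(proj, s, "I")
        f2 = attractor.stage_density_diff(shuffled, s, "I")
        assert np.allclose(f1.field, f2.field)

    def test_close_to_scipy_kde_for_round_clouds(self, rng):
        # cross-check against the covariance-bandwidth estimator on isotropic data
        normals = rng.normal(0, 1, size=(200, 2))
        tumors = rng.normal(5, 1, size=(200, 2))
        proj, s = self.proj_and_samples(normals, tumors)
        field = attractor.stage_density_diff(proj, s, "I")
        gx, gy = np.meshgrid(field.x, field.y)
        ref = gaussian_kde(normals.T)(np.vstack([gx.ravel(), gy.ravel()])).reshape(
            gx.shape
        ) - gaussian_kde(tumors.T)(np.vstack([gx.ravel(), gy.ravel()])).reshape(gx.shape)
        assert np.abs(field.field - ref).max() < 0.02

    def test_missing_stage_rejected(self, rng):
        proj, s = self.proj_and_samples(rng.normal(size=(5, 2)), rng.normal(size=(5, 2)), stage="I")
        with pytest.raises(ValidationError, match="stage II"):
            attractor.stage_density_diff(proj, s, "II")


class TestStageProgressionSummary:
    def test_identical_samples_zero_spread(self):
        proj = ProjectionTable(
            pd.DataFrame({"PC1": [2.0, 2.0], "PC2": [0.0, 0.0]}, index=["S0", "S1"])
        )
        s = samples_from(["tumor", "tumor"], stages=["III", "III"])
        out = attractor.stage_progression_summary(proj, s)
        assert len(out) == 1
        assert out.iloc[0]["sd_x1"] == 0.0

    def test_single_stage_single_row(self):
        proj = ProjectionTable(
            pd.DataFrame({"PC1": [1.0, 2.0, 5.0]}, index=["S0", "S1", "S2"])
        )
        s = samples_from(["normal", "tumor", "tumor"], stages=[pd.NA, "II", "II"])
        out = attractor.stage_progression_summary(proj, s)
        assert out["stage"].tolist() == ["II"]
        assert out.iloc[0]["mean_x1"] == pytest.approx(3.5)

    def test_planted_progression_recovered(self, desk_tissue):
        out = attractor.stage_progression_summary(
            desk_tissue["proj"], desk_tissue["samples"]
        )
        assert out["stage"].tolist() == ["I", "II", "III", "IV"]
        assert np.all(np.diff(out["mean_x1"]) > 0)
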