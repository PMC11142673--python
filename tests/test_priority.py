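"""Feature assembly, collinearity screen, PCA, priority index, classes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from corridorscape import (
    FeatureSpec,
    FeatureVariable,
    assemble_features,
    classify_priority,
    fit_pca,
    priority_scores,
    prioritize,
    screen_collinear,
    standardize,
)
from corridorscape.errors import ConfigError, DegenerateVariableError, JoinError


def simple_spec():
    return FeatureSpec(
        variables=(
            FeatureVariable("length_km", "corridor", invert=True),
            FeatureVariable("protection_pct", "corridor"),
            FeatureVariable("area_km2", "start"),
        ),
        drop_preference=(),
    )


def tables(n=3):
    corridors = pd.DataFrame(
        {
            "corridor_id": range(n),
            "start_id": [1] * n,
            "patch_id": [0] * n,
            "length_km": np.linspace(100, 300, n),
            "protection_pct": np.linspace(0, 100, n),
        }
    )
    starts = pd.DataFrame({"reserve_id": [1], "area_km2": [50.0]})
    ends = pd.DataFrame({"patch_id": [0], "elev_range_m": [700.0]})
    return corridors, starts, ends


class TestAssemble:
    def test_shape_and_column_order(self):
        c, s, e = tables(3)
        m = assemble_features(c, s, e, simple_spec())
        assert m.shape == (3, 3)
        assert list(m.columns) == ["corridor_length_km", "corridor_protection_pct",
                                   "start_area_km2"]

    def test_inverted_variable_negated(self):
        c, s, e = tables(3)
        m = assemble_features(c, s, e, simple_spec())
        assert m["corridor_length_km"].iloc[0] == -100.0

    def test_unmatched_join_is_error(self):
        c, s, e = tables(3)
        c.loc[1, "start_id"] = 99
        with pytest.raises(JoinError, match="99"):
            assemble_features(c, s, e, simple_spec())


class TestScreen:
    def test_identical_columns_one_dropped(self):
        rng = np.random.default_rng(0)
        x = rng.random(20)
        m = pd.DataFrame({"a": x, "b": x, "c": rng.random(20)})
        reduced, report = screen_collinear(m, 0.7)
        assert list(reduced.columns) == ["a", "c"]
        assert report["rho"].iloc[0] == pytest.approx(1.0)
        assert report["dropped"].iloc[0] == "b"

    def test_designated_drop_preference_respected(self):
        rng = np.random.default_rng(1)
        x = rng.random(30)
        m = pd.DataFrame({"length": x + rng.normal(0, 0.01, 30), "n_pas": x})
        reduced, report = screen_collinear(m, 0.7, drop_preference=("n_pas",))
        assert list(reduced.columns) == ["length"]
        assert report["dropped"].iloc[0] == "n_pas"

    def test_independent_columns_untouched(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.random((200, 4)), columns=list("abcd"))
        reduced, report = screen_collinear(m, 0.7)
        assert reduced.shape == m.shape
        assert len(report) == 0


class TestStandardize:
    def test_three_point_column(self):
        z, means, sds = standardize(pd.DataFrame({"x": [1.0, 2.0, 3.0],
                                                  "y": [0.0, 10.0, 20.0]}))
        np.testing.assert_allclose(z["x"], [-1.0, 0.0, 1.0])
        assert sds["x"] == pytest.approx(1.0)  # n-1 divisor

    def test_idempotent_within_tolerance(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.normal(5, 2, (50, 3)), columns=list("abc"))
        z1, *_ = standardize(m)
        z2, *_ = standardize(z1)
        np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-12)

    def test_columns_zero_mean_unit_sd(self):
        rng = np.random.default_rng(4)
        z, *_ = standardize(pd.DataFrame(rng.random((40, 5))))
        assert (z.mean().abs() < 1e-10).all()
        np.testing.assert_allclose(z.std(ddof=1), 1.0)

    def test_constant_column_named(self):
        with pytest.raises(DegenerateVariableError, match="flat"):
            standardize(pd.DataFrame({"flat": [1.0, 1.0, 1.0], "x": [1.0, 2.0, 3.0]}))


class TestPCA:
    def test_two_identical_variables(self):
        rng = np.random.default_rng(5)
        x = rng.random(50)
        z, *_ = standardize(pd.DataFrame({"a": x, "b": x}))
        model = fit_pca(z, n_components=2)
        assert model.eigenvalues[0] == pytest.approx(2.0)
        assert model.eigenvalues[1] == pytest.approx(0.0, abs=1e-10)

    def test_independent_columns_eigenvalues_near_one(self):
        rng = np.random.default_rng(6)
        z, *_ = standardize(pd.DataFrame(rng.normal(size=(4000, 4))))
        model = fit_pca(z)
        np.testing.assert_allclose(model.eigenvalues, 1.0, atol=0.1)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(7)
        z, *_ = standardize(pd.DataFrame(rng.random((30, 5))))
        model = fit_pca(z)
        gram = model.loadings.T @ model.loadings
        np.testing.assert_allclose(gram, np.eye(model.loadings.shape[1]), atol=1e-8)

    def test_matches_sklearn_eigenvalues(self):
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(8)
        z, *_ = standardize(pd.DataFrame(rng.random((60, 6))))
        model = fit_pca(z)
        sk = PCA(n_components=6).fit(z.to_numpy())
        np.testing.assert_allclose(model.eigenvalues, sk.explained_variance_,
                                   rtol=1e-8)


class TestPriorityScores:
    def fitted(self, n=40, p=5, seed=9):
        rng = np.random.default_rng(seed)
        raw = pd.DataFrame(rng.normal(size=(n, p)),
                           columns=[f"v{i}" for i in range(p)])
        raw["v1"] = raw["v0"] * 0.5 + rng.normal(size=n)  # some correlation
        z, *_ = standardize(raw)
        return fit_pca(z), z

    def test_mean_row_scores_zero(self):
        model, z = self.fitted()
        zero = pd.DataFrame(np.zeros((1, z.shape[1])), columns=z.columns)
        out = priority_scores(model, zero)
        assert out["index"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert out["priority_class"].iloc[0] == "low"

    def test_pythagoras(self):
        model, z = self.fitted()
        model.loadings = np.eye(z.shape[1])[:, :3]
        fake = pd.DataFrame([[3.0, 4.0, 0.0, 0.0, 0.0]], columns=z.columns)
        assert priority_scores(model, fake)["index"].iloc[0] == pytest.approx(5.0)

    def test_eigen_identity(self):
        model, z = self.fitted(n=80)
        out = priority_scores(model, z)
        lhs = (out["index"] ** 2).sum()
        rhs = (len(z) - 1) * model.eigenvalues[:3].sum()
        assert lhs == pytest.approx(rhs, rel=1e-6)

    def test_index_invariant_to_sign_flips(self):
        model, z = self.fitted()
        base = priority_scores(model, z)["index"]
        model.loadings = model.loadings * np.array([1, -1, 1])
        flipped = priority_scores(model, z)["index"]
        np.testing.assert_allclose(base, flipped, rtol=1e-12)

    def test_index_invariant_to_rotation_of_retained_space(self):
        model, z = self.fitted()
        base = priority_scores(model, z)["index"]
        rot = Rotation.from_euler("xyz", [0.4, -1.1, 2.2]).as_matrix()
        model.loadings = model.loadings @ rot
        rotated = priority_scores(model, z)["index"]
        np.testing.assert_allclose(base, rotated, rtol=1e-9)


class TestClassify:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.21, "low"), (1.999, "low"), (2.0, "medium"), (3.0, "medium"),
         (4.0, "medium"), (4.001, "high"), (7.11, "high")],
    )
    def test_boundaries(self, value, expected):
        assert classify_priority(value) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_priority(-0.1)

    @settings(derandomize=True, max_examples=200)
    @given(a=st.floats(0.0, 20.0), b=st.floats(0.0, 20.0))
    def test_class_order_monotone_in_index(self, a, b):
        """A larger index can never fall into a lower class."""
        order = {"low": 0, "medium": 1, "high": 2}
        lo, hi = sorted((a, b))
        assert order[classify_priority(lo)] <= order[classify_priority(hi)]


class TestPrioritizeEndToEnd:
    def test_classes_partition_and_paper_drop_pattern(self):
        rng = np.random.default_rng(10)
        n = 120
        length = rng.uniform(50, 400, n)
        corridors = pd.DataFrame(
            {
                "corridor_id": range(n),
                "start_id": rng.integers(0, 5, n),
                "patch_id": rng.integers(0, 4, n),
                "length_km": length,
                "elev_range_m": rng.uniform(1000, 3000, n),
                "protection_pct": rng.uniform(0, 100, n),
                # built collinear with length so the designated drop fires
                "n_pas": np.round(length / 20 + rng.normal(0, 1, n)),
                "n_kbas": rng.integers(0, 8, n),
                "mean_biomass": rng.uniform(20, 110, n),
            }
        )
        starts = pd.DataFrame(
            {"reserve_id": range(5), "area_km2": rng.uniform(5, 500, 5),
             "elev_range_m": rng.uniform(50, 400, 5)}
        )
        er = rng.uniform(300, 1500, 4)
        ends = pd.DataFrame(
            {"patch_id": range(4),
             # end area collinear with end elevation range -> designated drop
             "area_km2": er / 10 + rng.normal(0, 5, 4),
             "elev_range_m": er,
             "protection_pct": rng.uniform(0, 60, 4)}
        )
        model, results, report = prioritize(corridors, starts, ends)
        assert "corridor_n_pas" in set(report["dropped"])
        assert "corridor_n_pas" not in model.feature_names
        counts = results["priority_class"].value_counts()
        assert counts.sum() == n
        assert set(results["priority_class"]) <= {"low", "medium", "high"}
        assert (results["index"] >= 0).all()

    def test_too_few_informative_variables_rejected(self):
        corridors, starts, ends = tables(5)
        corridors["protection_pct"] = 1.0  # constant
        spec = FeatureSpec(
            variables=(
                FeatureVariable("length_km", "corridor", invert=True),
                FeatureVariable("protection_pct", "corridor"),
            ),
            drop_preference=(),
        )
        with pytest.raises(ConfigError):
            prioritize(corridors, starts, ends, spec)
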