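"""Cloud decision matrix construction, realization, and COPRAS ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from climacop import (
    BackwardCloudConfig,
    Cloud,
    CloudDecisionMatrix,
    DataError,
    DecisionMatrix,
    LikertDataset,
    WeightVector,
    apply_weights,
    build_cloud_decision_matrix,
    copras_rank,
    normalize_matrix,
    realize_decision_matrix,
)

from .conftest import make_dataset


def degenerate_cdm(ex):
    """Cloud matrix with En = He = 0 and the given expectations."""
    ex = np.asarray(ex, dtype=float)
    m, n = ex.shape
    return CloudDecisionMatrix(
        groups=[f"g{i}" for i in range(m)],
        criteria=[f"C{j + 1}" for j in range(n)],
        cells=[[Cloud(ex[i, j], 0.0, 0.0) for j in range(n)] for i in range(m)],
    )


class TestBuildCloudDecisionMatrix:
    def test_unanimous_group_yields_degenerate_cloud(self, two_criteria_spec):
        rows = [(4, 3)] * 12 + [(5, 2)] * 12
        ds = make_dataset(rows, attrs={"grp": ["A"] * 12 + ["B"] * 12})
        cdm = build_cloud_decision_matrix(
            ds, "grp", two_criteria_spec, BackwardCloudConfig(c=5, d=20), seed=0
        )
        assert cdm.cells[0][0].as_tuple() == (4.0, 0.0, 0.0)

    def test_grid_shape_matches_groups_and_criteria(self, two_criteria_spec):
        rng = np.random.default_rng(0)
        rows = rng.integers(1, 6, size=(40, 2))
        grp = ["A"] * 10 + ["B"] * 10 + ["C"] * 10 + ["D"] * 10
        ds = make_dataset(rows, attrs={"grp": grp})
        cdm = build_cloud_decision_matrix(
            ds, "grp", two_criteria_spec, BackwardCloudConfig(c=5, d=20), seed=1
        )
        assert cdm.shape == (4, 2)
        assert cdm.groups == ["A", "B", "C", "D"]

    def test_undersized_group_error_names_group(self, two_criteria_spec):
        rows = [(4, 3)] * 12 + [(5, 2)] * 2
        ds = make_dataset(rows, attrs={"grp": ["A"] * 12 + ["tiny"] * 2})
        with pytest.raises(DataError, match="tiny"):
            build_cloud_decision_matrix(
                ds, "grp", two_criteria_spec, BackwardCloudConfig(c=5, d=20), seed=0
            )

    def test_recovers_planted_group_means(self, two_criteria_spec):
        rng = np.random.default_rng(7)
        mu = {"A": (4.1, 2.4), "B": (3.4, 3.9)}
        rows, grp = [], []
        for g, (m1, m2) in mu.items():
            # continuous responses: isolates the backward transform from
            # rounding shrinkage
            block = np.column_stack(
                [rng.normal(m1, 0.3, 500), rng.normal(m2, 0.3, 500)]
            )
            rows.append(block)
            grp += [g] * 500
        ds = LikertDataset(
            ids=[f"r{i}" for i in range(1000)],
            attributes=pd.DataFrame({"grp": grp}),
            responses=pd.DataFrame(np.vstack(rows), columns=["C1", "C2"]),
        )
        cdm = build_cloud_decision_matrix(
            ds, "grp", two_criteria_spec, BackwardCloudConfig(c=30, d=200), seed=3
        )
        for i, g in enumerate(cdm.groups):
            for j in range(2):
                assert cdm.cells[i][j].ex == pytest.approx(mu[g][j], abs=0.05)


class TestRealize:
    def test_degenerate_clouds_realize_exactly(self):
        cdm = degenerate_cdm([[4.0, 2.0], [3.0, 5.0]])
        dm = realize_decision_matrix(cdm, 100, seed=0)
        assert np.array_equal(dm.values, [[4.0, 2.0], [3.0, 5.0]])

    def test_published_cell_realization_within_band(self):
        # 2,000 droplets from the published cell parameters stay within
        # ~3.3 standard errors of the expectation.
        cdm = CloudDecisionMatrix(
            ["g"], ["C1"], [[Cloud(4.3141, 0.6042, 0.0033)]]
        )
        dm = realize_decision_matrix(cdm, 2000, seed=0)
        assert dm.values[0, 0] == pytest.approx(4.3141, abs=0.045)

    def test_realization_unbiased_over_seeds(self):
        cloud = Cloud(4.0, 0.9, 0.1)
        cdm = CloudDecisionMatrix(["g"], ["C1"], [[cloud]])
        means = np.array(
            [realize_decision_matrix(cdm, 2000, seed=s).values[0, 0] for s in range(50)]
        )
        se = np.sqrt((cloud.en**2 + cloud.he**2) / 2000) / np.sqrt(50)
        assert abs(means.mean() - cloud.ex) < 3 * se

    def test_cell_substreams_are_independent_of_grid(self):
        # The same (group, criterion) index and master seed realize
        # identically regardless of other cells.
        a = realize_decision_matrix(degenerate_cdm([[4.0], [3.0]]), 10, seed=5)
        big = CloudDecisionMatrix(
            ["g0", "g1"],
            ["C1", "C2"],
            [
                [Cloud(4.0, 0.0, 0.0), Cloud(1.0, 0.5, 0.1)],
                [Cloud(3.0, 0.0, 0.0), Cloud(2.0, 0.5, 0.1)],
            ],
        )
        b = realize_decision_matrix(big, 10, seed=5)
        assert np.array_equal(a.values[:, 0], b.values[:, 0])


class TestNormalizeAndWeight:
    def test_column_normalization(self):
        dm = DecisionMatrix(["a", "b"], ["C1"], np.array([[2.0], [3.0]]))
        out = normalize_matrix(dm)
        assert np.allclose(out.values.ravel(), [0.4, 0.6])

    def test_single_alternative_normalizes_to_one(self):
        dm = DecisionMatrix(["a"], ["C1", "C2"], np.array([[2.0, 7.0]]))
        assert (normalize_matrix(dm).values == 1.0).all()

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_normalized_columns_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0.1, 5, size=(rng.integers(2, 6), rng.integers(1, 5)))
        dm = DecisionMatrix(
            [f"g{i}" for i in range(vals.shape[0])],
            [f"C{j}" for j in range(vals.shape[1])],
            vals,
        )
        out = normalize_matrix(dm)
        assert np.allclose(out.values.sum(axis=0), 1.0, atol=1e-9)

    def test_weighting_scales_columns(self):
        dm = DecisionMatrix(
            ["a", "b"], ["C1", "C2"], np.array([[0.4, 0.5], [0.6, 0.5]]), stage="normalized"
        )
        out = apply_weights(dm, WeightVector(np.array([1.0, 0.0]), "combined"))
        assert (out.values[:, 1] == 0).all()
        assert np.allclose(out.values[:, 0], [0.4, 0.6])

    def test_weighted_total_mass_is_one(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0.5, 5, size=(4, 3))
        dm = normalize_matrix(DecisionMatrix(list("abcd"), ["C1", "C2", "C3"], vals))
        w = WeightVector.normalized(rng.uniform(0.1, 1, 3), "combined")
        out = apply_weights(dm, w)
        assert out.values.sum() == pytest.approx(1.0, abs=1e-9)

    def test_nonpositive_column_is_error(self):
        dm = DecisionMatrix(["a", "b"], ["C1"], np.array([[1.0], [-1.0]]))
        with pytest.raises(DataError):
            normalize_matrix(dm)


class TestCoprasRank:
    def hand_example(self, spec):
        dm = DecisionMatrix(
            ["A", "B"], ["C1", "C2"], np.array([[0.3, 0.1], [0.2, 0.4]]), stage="weighted"
        )
        return copras_rank(dm, spec)

    def test_hand_computed_example(self, two_criteria_spec):
        res = self.hand_example(two_criteria_spec)
        assert np.allclose(res.Q, [0.7, 0.3])
        assert np.allclose(res.U, [1.0, 0.42857], atol=1e-4)
        assert res.rank.tolist() == [1, 2]

    def test_top_alternative_utility_is_exactly_one(self, two_criteria_spec):
        res = self.hand_example(two_criteria_spec)
        assert res.U[res.rank.argmin()] == 1.0

    def test_identical_alternatives_tie_at_utility_one(self, two_criteria_spec):
        dm = DecisionMatrix(
            ["A", "B"], ["C1", "C2"], np.array([[0.25, 0.25], [0.25, 0.25]]), stage="weighted"
        )
        res = copras_rank(dm, two_criteria_spec)
        assert np.allclose(res.U, 1.0)
        assert res.rank.tolist() == [1, 2]  # tie broken by group order

    def test_q_exceeds_p_when_cost_criteria_exist(self, two_criteria_spec):
        res = self.hand_example(two_criteria_spec)
        assert (res.Q > res.P).all()

    def test_zero_cost_sum_is_error(self, two_criteria_spec):
        dm = DecisionMatrix(
            ["A", "B"], ["C1", "C2"], np.array([[0.3, 0.0], [0.2, 0.4]]), stage="weighted"
        )
        with pytest.raises(DataError):
            copras_rank(dm, two_criteria_spec)

    def test_no_cost_criteria_degenerates_to_p(self):
        from climacop import CriteriaSpec

        spec = CriteriaSpec(
            ("C1", "C2"), {"C1": "f", "C2": "f"}, {"f": "benefit"}
        )
        dm = DecisionMatrix(
            ["A", "B"], ["C1", "C2"], np.array([[0.3, 0.1], [0.2, 0.4]]), stage="weighted"
        )
        res = copras_rank(dm, spec)
        assert np.allclose(res.Q, res.P)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_two_printed_forms_of_significance_agree(self, seed):
        # Q_i = P_i + R_min sum(R) / (R_i sum(R_min/R)) equals
        # Q_i = P_i + sum(R) / (R_i sum(1/R)): R_min cancels.
        rng = np.random.default_rng(seed)
        m = rng.integers(2, 7)
        P = rng.uniform(0.1, 1, m)
        R = rng.uniform(0.05, 1, m)
        q1 = P + R.min() * R.sum() / (R * (R.min() / R).sum())
        q2 = P + R.sum() / (R * (1.0 / R).sum())
        assert np.allclose(q1, q2, atol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(0, 10_000))
    def test_utility_in_unit_interval_and_ranks_permute(self, seed):
        from climacop import CriteriaSpec

        rng = np.random.default_rng(seed)
        m, n = rng.integers(2, 6), 4
        spec = CriteriaSpec(
            ("C1", "C2", "C3", "C4"),
            {"C1": "b", "C2": "b", "C3": "b", "C4": "c"},
            {"b": "benefit", "c": "cost"},
        )
        vals = rng.uniform(0.01, 1, size=(m, n))
        dm = normalize_matrix(
            DecisionMatrix([f"g{i}" for i in range(m)], list(spec.criteria), vals)
        )
        res = copras_rank(apply_weights(dm, WeightVector(np.full(n, 0.25), "x")), spec)
        assert ((res.U > 0) & (res.U <= 1)).all()
        assert res.U.max() == 1.0
        assert sorted(res.rank.tolist()) == list(range(1, m + 1))
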