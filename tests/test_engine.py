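import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import immusig as im
from immusig.core import ValidationError
from immusig.engine import build_contribution_matrix, normalize_compensation


def naive_ssgsea(values: pd.Series, gene_set, alpha: float) -> float:
    """Independent O(n^2) running-sum reference (assumes no tied values)."""
    order = np.argsort(-values.to_numpy(), kind="stable")
    genes = list(values.index[order])
    hits = set(gene_set) & set(genes)
    n = len(genes)
    n_miss = n - len(hits)
    weights = {g: (n - p) ** alpha for p, g in enumerate(genes) if g in hits}
    total = sum(weights.values())
    score = 0.0
    for k in range(n):
        p_hit = sum(weights[g] for g in genes[: k + 1] if g in hits) / total
        p_miss = sum(1 for g in genes[: k + 1] if g not in hits) / n_miss
        score += p_hit - p_miss
    return score


def brute_force_nnls(c: np.ndarray, es: np.ndarray):
    """Enumerate active sets; global optimum of min ||Cx - es|| s.t. x >= 0."""
    n = c.shape[1]
    best, best_obj = np.zeros(n), np.linalg.norm(es)
    for mask in range(1, 1 << n):
        free = [j for j in range(n) if mask >> j & 1]
        sol, *_ = np.linalg.lstsq(c[:, free], es, rcond=None)
        if (sol < -1e-9).any():
            continue
        x = np.zeros(n)
        x[free] = np.clip(sol, 0, None)
        obj = np.linalg.norm(c @ x - es)
        if obj < best_obj - 1e-12:
            best, best_obj = x, obj
    return best, best_obj


class TestDeviation:
    def test_self_deviation_is_zero_when_sample_is_sole_marking_reference(self):
        genes = ["g1", "g2"]
        rt = pd.DataFrame([[3.0, 9.0], [4.0, 7.0]], index=genes, columns=["A", "B"])
        st_ = pd.DataFrame([[1, 0], [1, 0]], index=genes, columns=["A", "B"])
        bundle = im.ReferenceBundle(["A", "B"], rt, st_, {"A": genes, "B": []})
        sample = rt["A"]
        d = im.compute_deviation(sample, bundle)
        np.testing.assert_allclose(d.to_numpy(), 0.0)

    def test_hand_computed_two_gene_case(self):
        genes = ["g1", "g2"]
        rt = pd.DataFrame([[3.0, 0.0], [0.0, 4.0]], index=genes, columns=["A", "B"])
        st_ = pd.DataFrame(np.eye(2), index=genes, columns=["A", "B"])
        bundle = im.ReferenceBundle(["A", "B"], rt, st_, {"A": ["g1"], "B": ["g2"]})
        d = im.compute_deviation(pd.Series([5.0, 2.0], index=genes), bundle)
        assert d.tolist() == [2.0, -2.0]

    def test_shared_marker_sums_over_marking_types(self):
        rt = pd.DataFrame([[1.0, 3.0]], index=["g"], columns=["A", "B"])
        st_ = pd.DataFrame([[1, 1]], index=["g"], columns=["A", "B"])
        bundle = im.ReferenceBundle(["A", "B"], rt, st_, {"A": ["g"], "B": ["g"]})
        d = im.compute_deviation(pd.Series([4.0], index=["g"]), bundle)
        assert d.tolist() == [(4 - 1) + (4 - 3)]

    def test_misaligned_sample_rejected(self, tiny_bundle):
        sample = pd.Series(1.0, index=list(tiny_bundle.marker_genes)[::-1])
        with pytest.raises(ValidationError):
            im.compute_deviation(sample, tiny_bundle)


class TestSsgsea:
    def test_worked_four_gene_example(self):
        values = pd.Series([10.0, 5.0, 2.0, 1.0], index=list("abcd"))
        assert im.ssgsea_score(values, ["a"], alpha=0.0) == pytest.approx(2.0)

    def test_bottom_set_scores_below_top_set(self):
        values = pd.Series(np.arange(10, 0, -1, dtype=float),
                           index=[f"g{i}" for i in range(10)])
        top = im.ssgsea_score(values, ["g0", "g1"], alpha=0.25)
        bottom = im.ssgsea_score(values, ["g8", "g9"], alpha=0.25)
        assert bottom < top

    def test_constant_profile_scores_zero_for_any_set(self):
        values = pd.Series(0.0, index=[f"g{i}" for i in range(8)])
        for gene_set in (["g0"], ["g3", "g7"], ["g1", "g2", "g6"]):
            assert im.ssgsea_score(values, gene_set, alpha=0.25) == pytest.approx(0.0)

    def test_empty_set_and_zero_overlap_error(self):
        values = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValidationError):
            im.ssgsea_score(values, [], alpha=0.25)
        with pytest.raises(ValidationError):
            im.ssgsea_score(values, ["zz"], alpha=0.25)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        values = pd.Series(rng.normal(size=n), index=[f"g{i}" for i in range(n)])
        gene_set = list(rng.choice(values.index, size=int(rng.integers(1, n)),
                                   replace=False))
        perm = values.sample(frac=1, random_state=int(rng.integers(1 << 16)))
        a = im.ssgsea_score(values, gene_set, alpha=0.25)
        b = im.ssgsea_score(perm, gene_set, alpha=0.25)
        assert a == pytest.approx(b, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_naive_running_sum(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        values = pd.Series(rng.normal(size=n), index=[f"g{i}" for i in range(n)])
        k = int(rng.integers(1, min(10, n)))
        gene_set = list(rng.choice(values.index, size=k, replace=False))
        alpha = float(rng.choice([0.0, 0.25, 1.0]))
        assert im.ssgsea_score(values, gene_set, alpha) == pytest.approx(
            naive_ssgsea(values, gene_set, alpha), abs=1e-9
        )


class TestScoreSample:
    def test_uplifted_type_has_maximal_score(self, tiny_bundle):
        sample = tiny_bundle.rt["B"] + 0.0
        sample.loc[["b1", "b2"]] += 5.0
        es = im.score_sample(sample, tiny_bundle)
        assert es.idxmax() == "B"

    def test_all_zero_deviation_gives_equal_scores(self, tiny_bundle):
        # a sample equal to the row-wise ST-weighted reference zeroes D
        rt, st_ = tiny_bundle.rt, tiny_bundle.st
        sample = (rt * st_).sum(axis=1) / st_.sum(axis=1)
        es = im.score_sample(sample, tiny_bundle)
        assert es.nunique() == 1

    def test_non_marker_genes_do_not_affect_scores(self, small_bundle):
        fr = im.random_fractions(3, small_bundle.cell_types, seed=5)
        expr, _ = im.generate_mixture(small_bundle, fr, noise_sd=0.0, seed=5)
        aligned = im.align_to_reference(
            im.transform_expression(expr), small_bundle
        ).matrix
        s1 = aligned.data.iloc[:, 0]
        es1 = im.score_sample(s1, small_bundle)
        es2 = im.score_sample(s1 + 0.0, small_bundle)  # identical sample
        pd.testing.assert_series_equal(es1, es2)


class TestContributionAndCompensation:
    def test_disjoint_bundle_diagonal_dominates_columns(self, tiny_bundle):
        m = build_contribution_matrix(tiny_bundle)
        arr = m.to_numpy()
        for j in range(arr.shape[1]):
            assert np.all(arr[j, j] >= arr[:, j])

    def test_identical_types_have_symmetric_entries(self):
        genes = ["g1", "g2", "g3", "g4"]
        rt = pd.DataFrame(
            [[9, 9], [8, 8], [2, 2], [1, 1]], index=genes, columns=["A", "B"],
            dtype=float,
        )
        st_ = pd.DataFrame([[1, 0], [0, 1], [1, 0], [0, 1]], index=genes,
                           columns=["A", "B"])
        bundle = im.ReferenceBundle(["A", "B"], rt, st_,
                                    {"A": ["g1", "g3"], "B": ["g2", "g4"]})
        m = build_contribution_matrix(bundle)
        assert m.loc["A", "B"] == pytest.approx(m.loc["A", "A"])
        assert m.loc["B", "A"] == pytest.approx(m.loc["B", "B"])

    def test_single_type_bundle_yields_1x1(self):
        rt = pd.DataFrame([[5.0], [1.0]], index=["g1", "g2"], columns=["A"])
        st_ = pd.DataFrame([[1], [1]], index=["g1", "g2"], columns=["A"])
        bundle = im.ReferenceBundle(["A"], rt, st_, {"A": ["g1", "g2"]})
        assert build_contribution_matrix(bundle).shape == (1, 1)

    def test_identity_contribution_maps_to_identity(self):
        c = pd.DataFrame(np.eye(3), index=list("ABC"), columns=list("ABC"))
        comp = normalize_compensation(c)
        np.testing.assert_allclose(comp.matrix.to_numpy(), np.eye(3))

    def test_large_off_diagonal_capped_at_half(self):
        c = pd.DataFrame([[2.0, 0.0], [4.0, 1.0]], index=["A", "B"],
                         columns=["A", "B"])
        comp = normalize_compensation(c)
        col = comp.matrix["A"]
        assert col["A"] == 1.0
        assert col["B"] == pytest.approx(0.5)

    def test_parent_child_entries_zeroed(self):
        h = im.CellTypeHierarchy({"A": frozenset({"B"})})
        c = pd.DataFrame(np.full((3, 3), 0.3) + np.eye(3) * 0.7,
                         index=list("ABC"), columns=list("ABC"))
        comp = normalize_compensation(c, h)
        assert comp.matrix.loc["A", "B"] == 0.0
        assert comp.matrix.loc["B", "A"] == 0.0
        assert comp.matrix.loc["C", "A"] > 0.0

    def test_zero_diagonal_rejected(self):
        c = pd.DataFrame([[0.0, 0.1], [0.2, 1.0]], index=["A", "B"],
                         columns=["A", "B"])
        with pytest.raises(ValidationError):
            normalize_compensation(c)


class TestCalibrate:
    def test_identity_feasible_optimum_passes_through(self):
        c = im.CompensationMatrix(pd.DataFrame(np.eye(2), index=["A", "B"],
                                               columns=["A", "B"]))
        out = im.calibrate(pd.Series([0.3, 0.7], index=["A", "B"]), c)
        np.testing.assert_allclose(out.to_numpy(), [0.3, 0.7])

    def test_negative_score_clamped_by_constraint(self):
        c = im.CompensationMatrix(pd.DataFrame(np.eye(2), index=["A", "B"],
                                               columns=["A", "B"]))
        out = im.calibrate(pd.Series([-0.2, 0.5], index=["A", "B"]), c)
        np.testing.assert_allclose(out.to_numpy(), [0.0, 0.5], atol=1e-12)

    def test_hand_solved_triangular_system(self):
        c = im.CompensationMatrix(pd.DataFrame([[1.0, 0.5], [0.0, 1.0]],
                                               index=["A", "B"], columns=["A", "B"]))
        out = im.calibrate(pd.Series([1.0, 1.0], index=["A", "B"]), c)
        np.testing.assert_allclose(out.to_numpy(), [0.5, 1.0], atol=1e-10)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_output_always_non_negative(self, seed):
        rng = np.random.default_rng(seed)
        m = np.eye(3)
        m[np.triu_indices(3, 1)] = rng.uniform(0, 0.25, size=3)
        c = im.CompensationMatrix(pd.DataFrame(m, index=list("ABC"),
                                               columns=list("ABC")))
        es = pd.Series(rng.normal(size=3), index=list("ABC"))
        out = im.calibrate(es, c)
        assert (out.to_numpy() >= 0).all()

    def test_all_negative_scores_give_zero_under_identity(self):
        c = im.CompensationMatrix(pd.DataFrame(np.eye(3), index=list("ABC"),
                                               columns=list("ABC")))
        out = im.calibrate(pd.Series([-1.0, -2.0, -0.5], index=list("ABC")), c)
        np.testing.assert_allclose(out.to_numpy(), 0.0)

    def test_non_finite_scores_rejected(self):
        c = im.CompensationMatrix(pd.DataFrame(np.eye(2), index=["A", "B"],
                                               columns=["A", "B"]))
        with pytest.raises(ValidationError):
            im.calibrate(pd.Series([np.nan, 1.0], index=["A", "B"]), c)


class TestEstimatePipeline:
    def test_identical_samples_give_identical_rows(self, small_bundle):
        col = small_bundle.rt.iloc[:, 0]
        data = pd.DataFrame({"s1": col, "s2": col})
        expr = im.ExpressionMatrix(data=data, platform="microarray")
        res = im.estimate(expr, small_bundle)
        np.testing.assert_allclose(res.calibrated.loc["s1"], res.calibrated.loc["s2"])

    def test_pure_sample_argmax_is_its_type(self, small_bundle):
        fractions = pd.DataFrame(
            np.eye(len(small_bundle.cell_types))[:3],
            index=["p1", "p2", "p3"], columns=small_bundle.cell_types,
        )
        expr, _ = im.generate_mixture(small_bundle, fractions, noise_sd=0.0, seed=0)
        res = im.estimate(expr, small_bundle)
        for i, sample in enumerate(["p1", "p2", "p3"]):
            assert res.calibrated.loc[sample].idxmax() == small_bundle.cell_types[i]

    def test_gene_and_sample_order_invariance(self, small_bundle):
        fr = im.random_fractions(4, small_bundle.cell_types, seed=9)
        expr, _ = im.generate_mixture(small_bundle, fr, noise_sd=0.2, seed=9)
        res1 = im.estimate(expr, small_bundle)
        shuffled = im.ExpressionMatrix(
            data=expr.data.sample(frac=1, random_state=0)
            .sample(frac=1, axis=1, random_state=1),
            platform=expr.platform,
        )
        res2 = im.estimate(shuffled, small_bundle)
        pd.testing.assert_frame_equal(
            res1.calibrated, res2.calibrated.loc[res1.calibrated.index]
        )

    def test_calibrated_is_non_negative(self, small_bundle):
        fr = im.random_fractions(6, small_bundle.cell_types, seed=2)
        expr, _ = im.generate_mixture(small_bundle, fr, seed=2)
        res = im.estimate(expr, small_bundle)
        assert (res.calibrated.to_numpy() >= 0).all()
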