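import itertools

import numpy as np
import pandas as pd
import pytest

from coocc.community import CommunityMatrix
from coocc.mechanism import (
    HABITAT_CALLS,
    TOLERANCE_CALLS,
    analyze_matrix,
    decide_mechanism,
    flag_driver_taxa,
    partner_taxa,
    pca_environment,
    permanova,
    tolerance_separation,
)
from coocc.nullmodel import checkerboard_units
from coocc.simulate import generate_env, plant_segregation


class TestDriverTaxa:
    def test_equal_cu_sums_give_no_driver(self, full_overlap):
        cb = checkerboard_units(full_overlap)
        assert flag_driver_taxa(cb).taxa == []

    def test_outlier_flagged_by_z_score(self):
        # synthetic per-taxon table: 8 taxa at 1 CU, one at 40
        cb = checkerboard_units(np.eye(2, dtype=int))  # shape only
        cb.per_taxon = pd.DataFrame(
            {"cu_sum": [1.0] * 8 + [40.0], "cu_mean": [0.1] * 8 + [4.0]},
            index=pd.Index([f"t{i}" for i in range(9)], name="taxon"),
        )
        out = flag_driver_taxa(cb)
        assert out.taxa == ["t8"]
        assert not out.below_threshold

    def test_fallback_to_max_contributor(self, abc_matrix):
        # CU sums 5,5,2: no z-score above 2 -> single max flagged with warning
        cb = checkerboard_units(abc_matrix)
        out = flag_driver_taxa(cb)
        assert out.below_threshold
        assert out.taxa in (["A"], ["B"])

    def test_partner_taxa_share_checkerboards(self, abc_matrix):
        cb = checkerboard_units(abc_matrix)
        assert partner_taxa(cb, "A") == ["B", "C"]


class TestToleranceSeparation:
    def test_similar_scores(self):
        tol = pd.Series({"d": 8.0, "p1": 7.0, "p2": 8.0, "p3": 9.0})
        out = tolerance_separation(["d"], ["p1", "p2", "p3"], tol)
        assert out.call == "similar"

    def test_differential_when_gap_at_least_three(self):
        tol = pd.Series({"d": 1.0, "p1": 8.0, "p2": 9.0})
        out = tolerance_separation(["d"], ["p1", "p2"], tol)
        assert out.call == "differential"
        assert out.gaps["gap"].min() >= 3

    def test_unknown_when_most_taxa_unscored(self):
        tol = pd.Series({"d": 5.0})
        out = tolerance_separation(["d"], ["p1", "p2", "p3"], tol)
        assert out.call == "unknown"

    def test_raw_gaps_always_reported(self):
        tol = pd.Series({"d": 2.0, "p1": 6.0})
        out = tolerance_separation(["d"], ["p1"], tol, gap_threshold=3.0)
        assert out.gaps["gap"].tolist() == [4.0]


class TestPCA:
    def test_rank_one_case_single_component(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal(8)
        env = pd.DataFrame(
            {"dissolved_oxygen": base, "ph": 2 * base, "temperature": -base},
            index=[f"s{i}" for i in range(8)],
        )
        out = pca_environment(env, n_components=3)
        assert out.proportion_variance[0] == pytest.approx(1.0, abs=1e-9)
        assert out.loadings.shape[1] == 1  # degenerate dims dropped, warned

    def test_matches_correlation_eigendecomposition(self):
        rng = np.random.default_rng(1)
        env = pd.DataFrame(
            rng.standard_normal((6, 4)),
            columns=["dissolved_oxygen", "temperature", "ph", "fetch"],
            index=[f"s{i}" for i in range(6)],
        )
        out = pca_environment(env, n_components=3)
        x = (env - env.mean()) / env.std(ddof=1)
        corr = np.cov(x.to_numpy().T, ddof=1)
        evals, evecs = np.linalg.eigh(corr)
        evals, evecs = evals[::-1], evecs[:, ::-1]
        assert out.sdev**2 == pytest.approx(evals[:3], abs=1e-9)
        for k in range(3):
            dot = abs(float(evecs[:, k] @ out.loadings.iloc[:, k]))
            assert dot == pytest.approx(1.0, abs=1e-9)

    def test_constant_variable_dropped(self):
        rng = np.random.default_rng(2)
        env = pd.DataFrame(
            rng.standard_normal((6, 3)),
            columns=["dissolved_oxygen", "temperature", "ph"],
        )
        env["sumrank"] = 7.0
        out = pca_environment(env)
        assert "sumrank" in out.dropped
        assert "sumrank" not in out.loadings.index

    def test_scores_centered_and_consistent(self):
        rng = np.random.default_rng(3)
        env = pd.DataFrame(
            rng.standard_normal((10, 5)),
            columns=["dissolved_oxygen", "temperature", "ph", "fetch",
                     "turbidity"],
        )
        out = pca_environment(env)
        assert np.allclose(out.scores.mean(axis=0), 0, atol=1e-12)
        # explained variance of the retained components
        assert out.proportion_variance.sum() <= 1 + 1e-12
        assert np.allclose(
            out.scores.var(ddof=1, axis=0), out.sdev**2, atol=1e-9
        )

    def test_sign_convention(self):
        rng = np.random.default_rng(4)
        env = pd.DataFrame(
            rng.standard_normal((7, 4)),
            columns=["dissolved_oxygen", "temperature", "ph", "fetch"],
        )
        out = pca_environment(env)
        for c in out.loadings.columns:
            col = out.loadings[c]
            assert col.iloc[np.argmax(np.abs(col.to_numpy()))] > 0


class TestPermanova:
    def test_exact_enumeration_matches_brute_force(self):
        x = np.array([0.0, 0.1, 0.3, 2.0, 2.2, 2.5])[:, None]
        labels = np.array([0, 0, 0, 1, 1, 1])
        res = permanova(x, labels, n_permutations=999, method="exact")
        assert res.method == "exact"
        assert res.n_permutations == 20

        def pseudo_f(lab):
            g1, g2 = x[lab == 0, 0], x[lab == 1, 0]
            gm = x[:, 0].mean()
            ssb = 3 * (g1.mean() - gm) ** 2 + 3 * (g2.mean() - gm) ** 2
            ssw = ((g1 - g1.mean()) ** 2).sum() + ((g2 - g2.mean()) ** 2).sum()
            return (ssb / 1) / (ssw / 4)

        fs = []
        for idx in itertools.combinations(range(6), 3):
            lab = np.ones(6, dtype=int)
            lab[list(idx)] = 0
            fs.append(pseudo_f(lab))
        f_obs = pseudo_f(labels)
        p_brute = np.mean([f >= f_obs - 1e-12 for f in fs])
        assert res.pseudo_f == pytest.approx(f_obs)
        assert res.p == pytest.approx(p_brute)

    def test_all_points_identical_indeterminate(self):
        res = permanova(np.ones((6, 2)), [0, 0, 0, 1, 1, 1])
        assert res.indeterminate and res.p == 1.0

    def test_zero_within_variance_infinite_f(self):
        x = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])[:, None]
        res = permanova(x, [0, 0, 0, 1, 1, 1], method="exact")
        assert res.infinite_f
        assert res.p == pytest.approx(2 / 20)  # only the two perfect splits

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            permanova(np.zeros((4, 2)), [0, 0, 0, 0])

    def test_invariant_to_group_relabeling_and_shift(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((9, 3))
        lab = np.array([0, 1, 0, 1, 0, 1, 0, 1, 0])
        a = permanova(x, lab, n_permutations=499, seed=9, method="permutation")
        b = permanova(x + 100.0, 1 - lab, n_permutations=499, seed=9,
                      method="permutation")
        assert a.pseudo_f == pytest.approx(b.pseudo_f)
        assert a.p == pytest.approx(b.p)

    def test_agrees_with_skbio_pseudo_f(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(6)
        x = rng.standard_normal((10, 3))
        lab = ["a"] * 5 + ["b"] * 5
        mine = permanova(x, lab, n_permutations=999, method="permutation")
        dm = skbio_stats.DistanceMatrix(
            squareform(pdist(x)), ids=[str(i) for i in range(10)]
        )
        ref = skbio_stats.permanova(dm, grouping=lab, permutations=999)
        assert mine.pseudo_f == pytest.approx(ref["test statistic"], rel=1e-9)
        assert abs(mine.p - ref["p-value"]) < 0.1  # both permutation MC


class TestDecideMechanism:
    def test_full_cross_product_is_exhaustive_and_consistent(self):
        negative_ok = {"competitive_exclusion", "differential_tolerance",
                       "differential_habitat", "indeterminate"}
        positive_ok = {"shared_habitat", "shared_tolerance",
                       "biological_homogenization", "indeterminate"}
        for cls, tol, hab in itertools.product(
            ("negative", "positive", "random"), TOLERANCE_CALLS, HABITAT_CALLS
        ):
            v = decide_mechanism(cls, tol, hab)
            if cls == "random":
                assert v.verdict == "neutral"
            elif cls == "negative":
                assert v.verdict in negative_ok
            else:
                assert v.verdict in positive_ok
            # purity: same inputs, same verdict
            assert decide_mechanism(cls, tol, hab).verdict == v.verdict

    @pytest.mark.parametrize(
        "cls,tol,hab,expected",
        [
            ("negative", "similar", "homogeneous", "competitive_exclusion"),
            ("negative", "similar", "different", "differential_habitat"),
            ("negative", "differential", "homogeneous", "differential_tolerance"),
            ("negative", "unknown", "homogeneous", "indeterminate"),
            ("negative", "similar", "unknown", "indeterminate"),
            ("positive", "similar", "homogeneous", "shared_habitat"),
            ("positive", "similar", "different", "shared_tolerance"),
            ("positive", "differential", "different", "biological_homogenization"),
            ("positive", "similar", "unknown", "indeterminate"),
            ("random", "differential", "different", "neutral"),
            ("unusable", "similar", "homogeneous", "indeterminate"),
        ],
    )
    def test_decision_table(self, cls, tol, hab, expected):
        assert decide_mechanism(cls, tol, hab).verdict == expected

    def test_invalid_call_rejected(self):
        with pytest.raises(ValueError):
            decide_mechanism("negative", "maybe", "unknown")


class TestAnalyzeMatrix:
    def test_random_classification_short_circuits_to_neutral(self, abc_matrix):
        v = analyze_matrix(abc_matrix, "random")
        assert v.verdict == "neutral"

    def test_missing_environment_gives_indeterminate(self):
        rng = np.random.default_rng(7)
        m = plant_segregation(10, 8, 2, fill=0.5, rng=rng)
        tol = {t: 5.0 for t in m.taxa}
        v = analyze_matrix(m, "negative", env=None, tolerances=tol)
        assert v.habitat_call == "unknown"
        assert v.verdict == "indeterminate"

    def test_planted_shift_recovered_as_differential_habitat(self):
        rng = np.random.default_rng(0)
        m = plant_segregation(12, 10, 2, fill=0.45, rng=rng)
        tol = {t: 5.0 for t in m.taxa}
        driver = m.cleanup_log["planted_pairs"][0][0]
        row = m.taxa.index(driver)
        focal = [m.sites[j] for j in range(m.n_sites) if m.cells[row, j]]
        env = generate_env(m.sites, 8, focal, shift=3.0, rng=rng)
        v = analyze_matrix(m, "negative", env=env, tolerances=tol, seed=1)
        assert v.verdict == "differential_habitat"

    def test_no_shift_recovered_as_competitive_exclusion(self):
        rng = np.random.default_rng(9)
        m = plant_segregation(12, 10, 2, fill=0.45, rng=rng)
        tol = {t: 5.0 for t in m.taxa}
        env = generate_env(m.sites, 8, [], shift=0.0, rng=rng)
        v = analyze_matrix(m, "negative", env=env, tolerances=tol, seed=1)
        assert v.verdict == "competitive_exclusion"
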