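import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as stn
from scipy import stats

from stemtrace import association as assoc
from stemtrace import synthetic
from stemtrace.io_formats import GeneSet


def bh_brute_force(p):
    """Literal step-up definition: q_i = min_{j: p_j >= p_i} p_j * m / rank_j, capped."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = min(running, 1.0)
    return q


class TestPearson:
    def test_exact_linearity(self):
        assert assoc.pearson([1, 2, 3], [2, 4, 6])[0] == pytest.approx(1.0)
        assert assoc.pearson([1, 2, 3], [3, 2, 1])[0] == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 4.0])
        r, p = assoc.pearson(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        r_direct = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert r == pytest.approx(r_direct, abs=1e-14)
        t = r_direct * np.sqrt(2 / (1 - r_direct**2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 2), abs=1e-12)

    def test_zero_variance_names_offender(self):
        with pytest.raises(ValueError, match="x has zero variance"):
            assoc.pearson([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError, match="y has zero variance"):
            assoc.pearson([1, 2, 3], [5, 5, 5])

    def test_input_validation(self):
        with pytest.raises(ValueError):
            assoc.pearson([1, 2], [1, 2])
        with pytest.raises(ValueError):
            assoc.pearson([1, 2, np.nan], [1, 2, 3])


class TestBHAdjust:
    def test_single_p_is_identity(self):
        assert assoc.bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            assoc.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04], atol=1e-12
        )

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(assoc.bh_adjust([0.2, 0.2, 0.2]), [0.2] * 3, atol=1e-12)

    def test_domain_enforced(self):
        for bad in ([0.0, 0.5], [1.2], [-0.1], [np.nan]):
            with pytest.raises(ValueError):
                assoc.bh_adjust(bad)

    @given(stn.integers(min_value=0, max_value=2**32 - 1))
    def test_matches_brute_force_definition(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-8, 1.0, size=rng.integers(1, 40))
        np.testing.assert_allclose(assoc.bh_adjust(p), bh_brute_force(p), atol=1e-12)

    def test_fdr_at_least_p(self, rng):
        p = rng.uniform(1e-6, 1, size=200)
        assert (assoc.bh_adjust(p) >= p - 1e-15).all()


def _scores_frame(values, ids):
    return pd.DataFrame({"stemness": values}, index=pd.Index(ids, name="sample_id"))


class TestCorrelateWithinGroups:
    def _cohort(self, rng, n=60, groups=("t1", "t2")):
        ids = [f"s{i}" for i in range(n * len(groups))]
        table = pd.DataFrame(
            {
                "sample_id": ids,
                "tissue": np.repeat(groups, n),
                "age_years": rng.choice([25, 35, 45, 55, 65, 75], size=n * len(groups)).astype(float),
            }
        )
        y = rng.normal(size=len(ids))
        return _scores_frame(y, ids), table

    def test_group_below_min_n_is_skipped(self, rng):
        scores, table = self._cohort(rng, n=30)
        extra = pd.DataFrame(
            {"sample_id": [f"x{i}" for i in range(29)], "tissue": "tiny",
             "age_years": rng.choice([25.0, 75.0], size=29)}
        )
        table = pd.concat([table, extra], ignore_index=True)
        scores = pd.concat(
            [scores, _scores_frame(rng.normal(size=29), extra["sample_id"])]
        )
        res, skipped = assoc.correlate_within_groups(scores, table, "age_years", min_n=30)
        assert set(res["group"]) == {"t1", "t2"}
        assert list(skipped["group"]) == ["tiny"] and int(skipped["n"].iloc[0]) == 29

    def test_identical_groups_get_identical_stats(self, rng):
        n = 40
        ids_a = [f"a{i}" for i in range(n)]
        ids_b = [f"b{i}" for i in range(n)]
        age = rng.choice([25, 45, 65], size=n).astype(float)
        y = rng.normal(size=n)
        table = pd.DataFrame(
            {"sample_id": ids_a + ids_b, "tissue": ["A"] * n + ["B"] * n,
             "age_years": np.tile(age, 2)}
        )
        scores = _scores_frame(np.tile(y, 2), ids_a + ids_b)
        res, _ = assoc.correlate_within_groups(scores, table, "age_years", min_n=10)
        a, b = res.set_index("group").loc["A"], res.set_index("group").loc["B"]
        assert a["r"] == pytest.approx(b["r"], abs=1e-14)
        assert a["p"] == pytest.approx(b["p"], abs=1e-14)
        assert a["fdr"] == pytest.approx(a["p"], abs=1e-14)

    def test_no_group_reaches_min_n_raises(self, rng):
        scores, table = self._cohort(rng, n=5)
        with pytest.raises(ValueError, match="min_n"):
            assoc.correlate_within_groups(scores, table, "age_years", min_n=50)

    def test_series_covariate_aligned_by_sample_id(self, rng):
        scores, table = self._cohort(rng, n=40)
        x = pd.Series(
            rng.normal(size=len(table)), index=table["sample_id"]
        )
        res, _ = assoc.correlate_within_groups(scores, table, x, min_n=10)
        assert len(res) == 2
        assert (res["n"] == 40).all()

    def test_null_simulation_controls_fdr(self):
        """With no age effect anywhere, tissue-level discoveries at FDR<0.05
        stay near the nominal rate across repetitions."""
        tissues = tuple(
            synthetic.TissueSpec(f"t{k}", n_samples=50, beta_age=0.0, sex_effect=0.0,
                                 shared_factor_loading=0.0)
            for k in range(5)
        )
        cfg = synthetic.SimulationConfig(
            n_genes=12, n_signature_genes=2, n_prolif_genes=2, n_senesc_genes=2,
            n_subjects=300, tissues=tissues,
        )
        n_reps, hits, total = 100, 0, 0
        for rep in range(n_reps):
            _, table, truth = synthetic.simulate_cohort(cfg, seed=1000 + rep)
            scores = _scores_frame(
                truth.latent.reindex(table["sample_id"]).to_numpy(), table["sample_id"]
            )
            res, _ = assoc.correlate_within_groups(scores, table, "age_years", min_n=50)
            hits += int((res["fdr"] < 0.05).sum())
            total += len(res)
        rate = hits / total
        mc_se = np.sqrt(0.05 * 0.95 / total)
        assert rate <= 0.05 + 3 * mc_se


class TestGeneSetSignals:
    def test_mean_of_present_genes(self):
        X = pd.DataFrame(
            [[2.0, 1.0], [4.0, 3.0], [10.0, 10.0]], index=["A", "B", "C"], columns=["s1", "s2"]
        )
        sig = assoc.gene_set_signal(X, GeneSet("S", frozenset({"A", "B"})))
        assert sig["s1"] == pytest.approx(3.0)
        assert sig["s2"] == pytest.approx(2.0)

    def test_partially_absent_set_warns(self):
        X = pd.DataFrame([[2.0], [4.0]], index=["A", "B"], columns=["s"])
        with pytest.warns(UserWarning, match="present"):
            sig = assoc.gene_set_signal(X, GeneSet("S", frozenset({"A", "x", "y"})))
        assert sig["s"] == pytest.approx(2.0)

    def test_full_set_equals_column_mean(self, tiny_expression):
        sig = assoc.gene_set_signal(
            tiny_expression, GeneSet("all", frozenset(tiny_expression.index))
        )
        np.testing.assert_allclose(sig.to_numpy(), tiny_expression.mean(axis=0).to_numpy())

    def test_no_overlap_raises(self, tiny_expression):
        with pytest.raises(KeyError):
            assoc.gene_set_signal(tiny_expression, GeneSet("S", frozenset({"zz"})))

    def test_singleton_set_equals_marker(self, tiny_expression):
        s1 = assoc.gene_set_signal(tiny_expression, GeneSet("m", frozenset({"B"})))
        s2 = assoc.marker_signal(tiny_expression, "B")
        np.testing.assert_array_equal(s1.to_numpy(), s2.to_numpy())

    def test_absent_marker_lists_near_matches(self, tiny_expression):
        with pytest.raises(KeyError, match="close matches"):
            assoc.marker_signal(tiny_expression, "AA")  # near-match of "A"


class TestCompareGroups:
    def test_identical_two_groups(self):
        v = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        g = pd.Series(["a"] * 3 + ["b"] * 3)
        res = assoc.compare_groups(v, g)
        assert res.test == "t"
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_welch_vs_pooled_differ_under_unequal_variance(self, rng):
        v = pd.Series(np.r_[rng.normal(0, 0.1, 20), rng.normal(0.5, 3.0, 8)])
        g = pd.Series(["a"] * 20 + ["b"] * 8)
        welch = assoc.compare_groups(v, g, pooled=False)
        pooled = assoc.compare_groups(v, g, pooled=True)
        assert welch.p != pooled.p

    def test_kruskal_matches_textbook_formula(self):
        v = pd.Series([1.0, 2, 3, 4, 5, 6, 7, 8, 9])
        g = pd.Series(["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        res = assoc.compare_groups(v, g)
        assert res.test == "kruskal-wallis"
        # no ties: H = 12/(N(N+1)) * sum R_g^2/n_g - 3(N+1)
        h = 12 / (9 * 10) * (6**2 / 3 + 15**2 / 3 + 24**2 / 3) - 3 * 10
        assert res.statistic == pytest.approx(h, abs=1e-12)

    def test_all_constant_multigroup_rejected(self):
        v = pd.Series([2.0] * 9)
        g = pd.Series(["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        with pytest.raises(ValueError, match="identical"):
            assoc.compare_groups(v, g)

    def test_small_group_rejected(self):
        v = pd.Series([1.0, 2.0, 3.0])
        g = pd.Series(["a", "a", "b"])
        with pytest.raises(ValueError, match="< 2"):
            assoc.compare_groups(v, g)


class TestDeriveProliferationSet:
    def test_recovers_marker_correlated_genes(self, rng):
        n = 200
        marker = rng.normal(size=50)
        vals = rng.normal(size=(n, 50))
        vals[:5] = marker + rng.normal(scale=0.05, size=(5, 50))  # tightly coupled block
        vals = np.exp(vals)
        genes = ["PCNA"] + [f"g{i}" for i in range(1, n)]
        X = pd.DataFrame(np.vstack([np.exp(marker), vals[1:]]), index=genes,
                         columns=[f"s{i}" for i in range(50)])
        got = assoc.derive_proliferation_set(X, "PCNA", top_frac=4 / (n - 1))
        assert "PCNA" not in got.genes
        assert got.genes == frozenset({"g1", "g2", "g3", "g4"})
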