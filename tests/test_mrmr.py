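import numpy as np
import pytest
from scipy import stats

from clinstrat import (
    integrate_union,
    redundancy,
    relevance_categorical,
    relevance_continuous,
    select_for_variable,
)
from clinstrat.mrmr import GreedyTrace, greedy_miq

from conftest import make_expression


def brute_force_mrmr(X, gene_ids, target, kind, k):
    """Independent step-by-step MIQ search: recomputes relevance, redundancy
    and phi from scratch at every step with scipy primitives."""
    if kind == "categorical":
        rel = []
        for row in X:
            groups = [row[target == g] for g in np.unique(target)]
            f = stats.f_oneway(*groups).statistic
            rel.append(0.0 if np.isnan(f) else float(f))
    else:
        rel = [abs(stats.pearsonr(row, target).statistic) for row in X]
    rel = np.asarray(rel)
    ids = list(gene_ids)
    remaining = sorted(range(len(ids)), key=lambda i: (-rel[i], ids[i]))
    selected = [remaining.pop(0)]
    while len(selected) < k:
        best = None
        for i in remaining:
            r = np.mean([abs(stats.pearsonr(X[i], X[j]).statistic) for j in selected])
            phi = rel[i] / max(r, 1e-12)
            key = (-phi, -rel[i], ids[i])
            if best is None or key < best[0]:
                best = (key, i)
        selected.append(best[1])
        remaining.remove(best[1])
    return [ids[i] for i in selected]


class TestRelevanceCategorical:
    def test_closed_form_f(self):
        gene = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        assert relevance_categorical(gene, labels) == pytest.approx(13.5, abs=1e-12)

    def test_matches_scipy(self, rng):
        for _ in range(20):
            gene = rng.normal(size=30)
            labels = rng.choice(["x", "y", "z"], size=30)
            expected = stats.f_oneway(*[gene[labels == g] for g in "xyz"]).statistic
            assert relevance_categorical(gene, labels) == pytest.approx(expected, rel=1e-10)

    def test_equal_group_means_zero(self):
        assert relevance_categorical(
            np.array([1.0, 3.0, 2.0, 2.0]), np.array(["a", "a", "b", "b"])
        ) == 0.0

    def test_single_group_errors(self):
        with pytest.raises(ValueError, match="2"):
            relevance_categorical(np.array([1.0, 2.0]), np.array(["a", "a"]))

    def test_degenerate_grouping_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            relevance_categorical(np.array([1.0, 2.0, 3.0]), np.array(["a", "b", "c"]))

    def test_singleton_groups_allowed(self):
        f = relevance_categorical(
            np.array([1.0, 2.0, 3.0, 9.0]), np.array(["a", "a", "a", "b"])
        )
        assert np.isfinite(f) and f > 0


class TestRelevanceContinuous:
    def test_self_is_one(self, rng):
        x = rng.normal(size=10)
        assert relevance_continuous(x, x) == pytest.approx(1.0)

    def test_negation_is_one(self, rng):
        x = rng.normal(size=10)
        assert relevance_continuous(x, -x) == pytest.approx(1.0)

    def test_hand_computed_pcc(self):
        # PCC([1,2,3],[1,2,4]) = 3 / sqrt(2 * 14/3)
        expected = 3 / np.sqrt(2 * 14 / 3)
        assert relevance_continuous(
            np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 4.0])
        ) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.982, abs=5e-4)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            relevance_continuous(np.ones(5), np.arange(5.0))


class TestRedundancy:
    def test_copy_of_self_is_one(self, rng):
        x = rng.normal(size=20)
        assert redundancy(x, x[None, :]) == pytest.approx(1.0)

    def test_mean_of_abs_correlations(self, rng):
        x = rng.normal(size=50)
        a, b = rng.normal(size=(2, 50))
        expected = np.mean(
            [abs(stats.pearsonr(x, a).statistic), abs(stats.pearsonr(x, b).statistic)]
        )
        assert redundancy(x, np.vstack([a, b])) == pytest.approx(expected, rel=1e-10)

    def test_orthogonal_noise_near_zero(self, rng):
        x = rng.normal(size=5000)
        y = rng.normal(size=5000)
        assert redundancy(x, y[None, :]) < 0.05


class TestGreedySearch:
    def test_documented_three_gene_example(self):
        """relevances (0.9, 0.8, 0.5), |r12|=0.95, |r13|=0.10, |r23|=0.20:
        phi prefers the weakly relevant but near-orthogonal g3 at step 2."""
        rel = np.array([0.9, 0.8, 0.5])
        ids = np.array(["g1", "g2", "g3"])
        corr = np.array([[1.0, 0.95, 0.10], [0.95, 1.0, 0.20], [0.10, 0.20, 1.0]])
        trace = greedy_miq(rel, ids, lambda i: corr[i], 3)
        assert [t.gene_id for t in trace] == ["g1", "g3", "g2"]
        assert trace[0].phi == pytest.approx(0.9)
        assert trace[1].phi == pytest.approx(0.5 / 0.10)
        assert trace[2].redundancy_R == pytest.approx((0.95 + 0.20) / 2)

    def test_matches_bruteforce_on_random_instances(self, rng):
        for trial in range(60):
            p = int(rng.integers(4, 13))
            n = int(rng.integers(12, 25))
            k = int(rng.integers(1, min(p, 5) + 1))
            X = rng.normal(size=(p, n))
            ids = [f"g{i:02d}" for i in range(p)]
            expr = make_expression(X, gene_ids=ids)
            if trial % 2:
                kind = "categorical"
                target = rng.choice(["a", "b", "c"], size=n)
                if len(np.unique(target)) < 2:
                    continue
            else:
                kind = "continuous"
                target = rng.normal(size=n)
            import pandas as pd

            series = pd.Series(target, index=expr.sample_ids, name="v")
            trace = select_for_variable(expr, series, kind, pool=p, k=k)
            expected = brute_force_mrmr(X, ids, np.asarray(target), kind, k)
            assert [t.gene_id for t in trace] == expected

    def test_pool_restriction_and_containment(self, rng):
        import pandas as pd

        X = rng.normal(size=(10, 40))
        expr = make_expression(X)
        y = pd.Series(rng.normal(size=40), index=expr.sample_ids, name="v")
        from clinstrat.mrmr import relevance_all

        rel = relevance_all(X, y, "continuous")
        top2 = set(np.asarray(expr.gene_ids)[np.argsort(-rel)[:2]])
        trace = select_for_variable(expr, y, "continuous", pool=2, k=2)
        assert {t.gene_id for t in trace} == top2

    def test_k_one_is_max_relevance(self, rng):
        import pandas as pd

        X = rng.normal(size=(6, 30))
        expr = make_expression(X)
        y = pd.Series(X[3] + rng.normal(scale=0.1, size=30), index=expr.sample_ids, name="v")
        trace = select_for_variable(expr, y, "continuous", pool=6, k=1)
        assert len(trace) == 1
        assert trace[0].gene_id == "g3"
        assert trace[0].phi == trace[0].relevance_D

    def test_k_exceeding_pool_errors(self, small_bundle):
        clin = small_bundle.clinical
        with pytest.raises(ValueError):
            select_for_variable(
                small_bundle.expression, clin.data["cont_1"], "continuous", pool=3, k=5
            )

    def test_redundancy_in_unit_interval_after_step_one(self, small_bundle):
        trace = select_for_variable(
            small_bundle.expression,
            small_bundle.clinical.data["cat_1"],
            "categorical",
            pool=50,
            k=10,
        )
        assert trace[0].redundancy_R == 0.0
        for t in trace[1:]:
            assert 0.0 <= t.redundancy_R <= 1.0
        assert all(np.isfinite(t.phi) for t in trace)


class TestIntegrateUnion:
    @staticmethod
    def _traces(genes):
        return [GreedyTrace(i + 1, g, 1.0, 0.0, 1.0) for i, g in enumerate(genes)]

    def test_union_dedup(self):
        union = integrate_union(
            {"v1": self._traces(["a", "b", "c"]), "v2": self._traces(["b", "c", "d"])}
        )
        assert union == ["a", "b", "c", "d"]

    def test_single_variable_identity(self):
        assert integrate_union({"v": self._traces(["x", "y"])}) == ["x", "y"]

    def test_size_bounded_by_qk(self, small_bundle):
        from clinstrat import select_all_variables

        res = select_all_variables(small_bundle.expression, small_bundle.clinical, pool=60, k=12)
        q = len(small_bundle.clinical.data.columns)
        assert 12 <= len(res.union_genes) <= q * 12
        assert len(res.union_genes) == len(set(res.union_genes))
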