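"""NMF subtype classification, cluster naming, consensus and association."""

from itertools import permutations, product

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.special import comb
from sklearn.metrics import adjusted_rand_score

from aldhnet.subtypes import (
    SignatureScheme,
    association_tests,
    classify_scheme,
    consensus_aggressive,
    default_schemes,
    map_clusters_to_subtypes,
    nmf_classify,
)


def _planted_expr(n_per_cluster=30, seed=0):
    """Block-diagonal two-cluster matrix on a toy 2-subtype scheme."""
    rng = np.random.default_rng(seed)
    genes_a = [f"A{i}" for i in range(15)]
    genes_b = [f"B{i}" for i in range(15)]
    scheme = SignatureScheme(
        name="toy",
        subtype_genes={"alpha": tuple(genes_a), "beta": tuple(genes_b)},
        aggressive_label="alpha",
    )
    n = 2 * n_per_cluster
    expr = pd.DataFrame(
        rng.uniform(0, 0.5, (30, n)),
        index=genes_a + genes_b,
        columns=[f"s{i}" for i in range(n)],
    )
    expr.iloc[:15, :n_per_cluster] += 4.0
    expr.iloc[15:, n_per_cluster:] += 4.0
    truth = np.array([0] * n_per_cluster + [1] * n_per_cluster)
    return expr, truth, scheme


class TestNMF:
    def test_planted_blocks_recovered(self):
        expr, truth, scheme = _planted_expr()
        clusters = nmf_classify(expr, scheme, seed=1, n_restarts=5)
        assert adjusted_rand_score(truth, clusters.to_numpy()) >= 0.9

    def test_k1_rejected(self):
        with pytest.raises(ValueError, match="k >= 2"):
            SignatureScheme(
                name="bad", subtype_genes={"only": ("g1",)}, aggressive_label="only"
            )

    def test_duplicated_samples_co_cluster(self):
        expr, _, scheme = _planted_expr(n_per_cluster=10)
        dup = pd.concat(
            [expr, expr.add_suffix("_dup", axis=1)], axis=1
        )
        clusters = nmf_classify(dup, scheme, seed=2, n_restarts=5)
        for s in expr.columns:
            assert clusters[s] == clusters[f"{s}_dup"]

    def test_sample_order_invariant(self):
        expr, _, scheme = _planted_expr(n_per_cluster=10)
        shuffled = expr.iloc[:, ::-1]
        c1 = classify_scheme(expr, scheme, seed=3, n_restarts=5)
        c2 = classify_scheme(shuffled, scheme, seed=3, n_restarts=5)
        assert (c1.sort_index() == c2.sort_index()).all()

    def test_insufficient_overlap_reports_match_count(self):
        expr, _, scheme = _planted_expr()
        expr5 = expr.iloc[:5]
        with pytest.raises(ValueError, match="only 5 of 30"):
            nmf_classify(expr5, scheme)

    def test_determinism(self):
        expr, _, scheme = _planted_expr()
        c1 = nmf_classify(expr, scheme, seed=4, n_restarts=3)
        c2 = nmf_classify(expr, scheme, seed=4, n_restarts=3)
        assert (c1 == c2).all()


class TestClusterMapping:
    def test_identity_and_permutation_recovered(self):
        expr, truth, scheme = _planted_expr()
        clusters = pd.Series(truth, index=expr.columns)
        mapping = map_clusters_to_subtypes(expr, clusters, scheme)
        assert mapping == {0: "alpha", 1: "beta"}
        permuted = pd.Series(1 - truth, index=expr.columns)
        mapping_p = map_clusters_to_subtypes(expr, permuted, scheme)
        assert mapping_p == {0: "beta", 1: "alpha"}

    def test_assignment_matches_exhaustive_permutation_search(self, rng):
        """Hungarian result equals brute force over all 3x3 permutations."""
        corr = rng.normal(0, 1, (3, 3))
        row, col = linear_sum_assignment(-corr)
        hungarian_total = corr[row, col].sum()
        brute_best = max(
            sum(corr[i, p[i]] for i in range(3)) for p in permutations(range(3))
        )
        assert hungarian_total == pytest.approx(brute_best)


class TestConsensus:
    @staticmethod
    def _schemes4():
        def mk(name, agg, other):
            return SignatureScheme(
                name=name,
                subtype_genes={agg: (f"{name}_a",), other: (f"{name}_o",)},
                aggressive_label=agg,
            )

        return [
            mk("m", "basal-like", "classical"),
            mk("c", "quasi-mesenchymal", "classical"),
            mk("b", "squamous", "progenitor"),
            mk("x", "basal-A", "basal-B"),
        ]

    def test_three_of_four_is_aggressive(self):
        schemes = self._schemes4()
        calls = pd.DataFrame(
            {
                "m": ["basal-like"],
                "c": ["quasi-mesenchymal"],
                "b": ["squamous"],
                "x": ["basal-B"],
            },
            index=["s1"],
        )
        out = consensus_aggressive(calls, schemes, threshold=3)
        assert bool(out.loc["s1", "consensus_aggressive"])

    def test_all_favorable_is_not(self):
        schemes = self._schemes4()
        calls = pd.DataFrame(
            {"m": ["classical"], "c": ["classical"], "b": ["progenitor"],
             "x": ["basal-B"]},
            index=["s1"],
        )
        out = consensus_aggressive(calls, schemes, threshold=3)
        assert not bool(out.loc["s1", "consensus_aggressive"])

    def test_exhaustive_truth_table(self):
        """All 2^4 aggressive/favourable patterns match direct counting."""
        schemes = self._schemes4()
        agg = {s.name: s.aggressive_label for s in schemes}
        fav = {"m": "classical", "c": "classical", "b": "progenitor", "x": "basal-B"}
        rows, expected = [], []
        for pattern in product([0, 1], repeat=4):
            rows.append(
                {
                    s.name: agg[s.name] if bit else fav[s.name]
                    for s, bit in zip(schemes, pattern)
                }
            )
            expected.append(sum(pattern))
        calls = pd.DataFrame(rows)
        out = consensus_aggressive(calls, schemes, threshold=3)
        assert out["aggressive_count"].tolist() == expected
        assert out["consensus_aggressive"].tolist() == [e >= 3 for e in expected]

    def test_threshold_above_scheme_count_rejected(self):
        schemes = self._schemes4()[:2]
        calls = pd.DataFrame({"m": ["classical"], "c": ["classical"]})
        with pytest.raises(ValueError, match="exceeds"):
            consensus_aggressive(calls, schemes, threshold=3)


def fisher_oracle(table):
    """Two-sided Fisher p by hypergeometric enumeration at fixed margins."""
    a, b = table[0]
    c, d = table[1]
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d

    def prob(x):
        return (
            comb(r1, x, exact=True)
            * comb(r2, c1 - x, exact=True)
            / comb(n, c1, exact=True)
        )

    p_obs = prob(a)
    return sum(
        prob(x)
        for x in range(max(0, c1 - r2), min(r1, c1) + 1)
        if prob(x) <= p_obs * (1 + 1e-9)
    )


class TestAssociation:
    def test_perfect_association_extreme_p(self):
        groups = ["High"] * 10 + ["Low"] * 10
        flags = [True] * 10 + [False] * 10
        scores = [1.0] * 10 + [-1.0] * 10
        out = association_tests(groups, flags, scores)
        assert out["p"] < 1e-4

    def test_fisher_matches_hypergeometric_enumeration(self):
        groups = ["High"] * 4 + ["Low"] * 4
        flags = [True, True, True, False, True, False, False, False]
        scores = np.arange(8.0)
        out = association_tests(groups, flags, scores)
        assert out["test"] == "fisher"
        assert out["p"] == pytest.approx(fisher_oracle([[3, 1], [1, 3]]))

    def test_null_chi2_p_uniform(self):
        """Chi-squared p-values are uniform under independent margins."""
        from scipy import stats

        rng = np.random.default_rng(17)
        pvals = []
        trials = 0
        while len(pvals) < 400 and trials < 4000:
            trials += 1
            groups = np.where(rng.random(80) < 0.5, "High", "Low")
            flags = rng.random(80) < 0.5
            try:
                out = association_tests(groups, flags, rng.normal(0, 1, 80))
            except ValueError:
                continue
            if out["test"] == "chi2":
                pvals.append(out["p"])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            association_tests(["High"] * 4, [True, False] * 2, np.arange(4.0))


def test_default_schemes_match_generator_blocks(cohort):
    expr, _ = cohort
    for scheme in default_schemes():
        assert all(g in expr.index for g in scheme.genes)
        assert scheme.k in (2, 3, 4)
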