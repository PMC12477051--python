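"""Peak annotation, TSS profiles, feature-distribution test, intersections."""

import numpy as np
import pandas as pd
import pytest

from aldhnet.genomic import (
    annotate_peaks,
    feature_distribution_test,
    multiway_intersection,
    overlap_fraction,
    promoter_peak_genes,
    tss_distance_profile,
)


def _ann(records):
    return pd.DataFrame(
        records, columns=["gene", "chrom", "strand", "tss", "body_start", "body_end"]
    )


def _peaks(intervals):
    df = pd.DataFrame(intervals, columns=["chrom", "start", "end"])
    df["name"] = [f"p{i}" for i in range(len(df))]
    return df


TOY_ANN = _ann(
    [
        ("gA", "chr1", "+", 10_000, 10_000, 30_000),
        ("gB", "chr1", "-", 90_000, 70_000, 90_000),
        ("gC", "chr2", "+", 5_000, 5_000, 12_000),
    ]
)


class TestAnnotate:
    def test_midpoint_at_tss_is_promoter_distance_zero(self):
        out = annotate_peaks(_peaks([("chr1", 9_900, 10_100)]), TOY_ANN)
        row = out.table.iloc[0]
        assert row["gene"] == "gA"
        assert row["distance"] == 0
        assert row["feature"] == "promoter"

    def test_far_peak_is_distal_intergenic(self):
        out = annotate_peaks(_peaks([("chr1", 49_900, 50_100)]), TOY_ANN)
        row = out.table.iloc[0]
        assert row["feature"] == "distal intergenic"
        assert abs(row["distance"]) == 40_000

    def test_strand_aware_sign(self):
        # 1 kb downstream of gA's plus-strand TSS: positive distance
        out = annotate_peaks(_peaks([("chr1", 10_900, 11_100)]), TOY_ANN)
        assert out.table.iloc[0]["distance"] == 1_000
        # 1 kb "after" gB's minus-strand TSS going left: positive too
        out = annotate_peaks(_peaks([("chr1", 88_900, 89_100)]), TOY_ANN)
        assert out.table.iloc[0]["gene"] == "gB"
        assert out.table.iloc[0]["distance"] == 1_000

    def test_intronic_and_exonic_classes(self):
        peaks = _peaks([("chr1", 19_900, 20_100)])  # inside gA body, 10 kb from TSS
        out = annotate_peaks(peaks, TOY_ANN)
        assert out.table.iloc[0]["feature"] == "intronic"
        out2 = annotate_peaks(
            peaks, TOY_ANN, exons={"gA": [(19_000, 21_000)]}
        )
        assert out2.table.iloc[0]["feature"] == "exonic"

    def test_unknown_chromosome_flagged(self):
        with pytest.warns(UserWarning, match="unassigned"):
            out = annotate_peaks(_peaks([("chrX", 0, 200)]), TOY_ANN)
        assert out.table.iloc[0]["gene"] is None
        assert out.assigned.empty

    def test_random_peaks_match_brute_force_nearest_tss(self, rng):
        """Nearest-TSS assignment equals the O(n*m) exhaustive scan."""
        chroms = ["chr1", "chr2"]
        ann = TOY_ANN
        peaks = []
        for _ in range(20):
            c = chroms[int(rng.integers(2))]
            s = int(rng.integers(0, 100_000))
            peaks.append((c, s, s + 200))
        out = annotate_peaks(_peaks(peaks), ann)
        for (_, row) in out.table.iterrows():
            mid = (row["start"] + row["end"]) // 2
            cand = ann[ann["chrom"] == row["chrom"]]
            best = min(abs(mid - t) for t in cand["tss"])
            assert abs(row["distance"]) == best

    def test_empty_annotation_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            annotate_peaks(_peaks([("chr1", 0, 100)]), TOY_ANN.iloc[0:0])


class TestTSSProfile:
    def test_constant_distance(self):
        peaks = _peaks([("chr1", 10_900, 11_100)] * 5)
        profile = tss_distance_profile(annotate_peaks(peaks, TOY_ANN))
        assert profile["median"] == 1_000
        occupied = [k for k, v in profile["histogram"].items() if v]
        assert occupied == ["[1000,10000)"]

    def test_median_of_three(self):
        peaks = _peaks(
            [
                ("chr1", 9_910, 10_110),  # 10 bp
                ("chr1", 10_900, 11_100),  # 1 kb
                ("chr1", 109_900, 110_100),  # ~100 kb from gB (minus strand)
            ]
        )
        profile = tss_distance_profile(annotate_peaks(peaks, TOY_ANN))
        assert profile["median"] == 1_000

    def test_log_uniform_median_recovered(self, rng):
        """Sampled |distances| reproduce the generative median within 10%."""
        d = 10 ** rng.uniform(1, 5, 2000)
        ann = _ann([("g", "chr1", "+", 1_000_000, 1_000_000, 1_010_000)])
        peaks = _peaks(
            [("chr1", int(1_000_000 + x) - 100, int(1_000_000 + x) + 100) for x in d]
        )
        profile = tss_distance_profile(annotate_peaks(peaks, ann))
        assert profile["median"] == pytest.approx(10**3, rel=0.10)

    def test_all_unassigned_rejected(self):
        with pytest.warns(UserWarning):
            out = annotate_peaks(_peaks([("chrZ", 0, 100)]), TOY_ANN)
        with pytest.raises(ValueError, match="no assigned"):
            tss_distance_profile(out)


class TestFeatureDistribution:
    def test_identical_proportions_statistic_zero(self):
        a = {"promoter": 10, "exonic": 20, "intronic": 30, "distal intergenic": 40}
        b = {k: 2 * v for k, v in a.items()}
        out = feature_distribution_test(a, b)
        assert out["statistic"] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_categories_extreme(self):
        a = {"promoter": 500, "exonic": 500, "intronic": 0, "distal intergenic": 0}
        b = {"promoter": 0, "exonic": 0, "intronic": 500, "distal intergenic": 500}
        assert feature_distribution_test(a, b)["p"] < 1e-6

    def test_matches_direct_formula(self, rng):
        a = dict(zip(
            ("promoter", "exonic", "intronic", "distal intergenic"),
            rng.integers(5, 100, 4),
        ))
        b = dict(zip(
            ("promoter", "exonic", "intronic", "distal intergenic"),
            rng.integers(5, 100, 4),
        ))
        out = feature_distribution_test(a, b)
        # direct sum((O-E)^2 / E)
        obs = np.array([list(a.values()), list(b.values())], dtype=float)
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        assert out["statistic"] == pytest.approx(((obs - exp) ** 2 / exp).sum())
        assert out["df"] == 3

    def test_zero_class_collapsed_with_warning(self):
        a = {"promoter": 10, "exonic": 0, "intronic": 5, "distal intergenic": 5}
        b = {"promoter": 5, "exonic": 0, "intronic": 10, "distal intergenic": 5}
        with pytest.warns(UserWarning, match="collapsing"):
            out = feature_distribution_test(a, b)
        assert out["df"] == 2


class TestOverlap:
    def test_subset_gives_one(self):
        assert overlap_fraction({"a", "b"}, {"a", "b", "c"})["fraction"] == 1.0

    def test_counts_match_membership(self, rng):
        universe = [f"g{i}" for i in range(50)]
        de = set(rng.choice(universe, 20, replace=False))
        pk = set(rng.choice(universe, 30, replace=False))
        out = overlap_fraction(de, pk)
        assert out["overlap"] == sum(1 for g in de if g in pk)
        assert out["fraction"] == out["overlap"] / 20

    def test_adding_peak_gene_never_decreases(self, rng):
        de = {f"g{i}" for i in range(10)}
        pk = {f"g{i}" for i in range(0, 20, 2)}
        before = overlap_fraction(de, pk)["fraction"]
        after = overlap_fraction(de, pk | {"g1"})["fraction"]
        assert after >= before

    def test_empty_de_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            overlap_fraction(set(), {"a"})


class TestMultiway:
    def test_shared_candidates(self):
        sets = {
            "rna_up": {"RUNX2", "CD55", "X1"},
            "atac_open": {"RUNX2", "CD55", "Y1"},
            "fosl2_open": {"RUNX2", "CD55", "Z1"},
        }
        out = multiway_intersection(sets)
        assert out["gene"].tolist() == ["CD55", "RUNX2"]
        assert (out["n_sets"] == 3).all()

    def test_min_sets_one_is_union(self):
        sets = {"a": {"X"}, "b": {"Y"}}
        out = multiway_intersection(sets, min_sets=1)
        assert set(out["gene"]) == {"X", "Y"}

    def test_matches_brute_force_counts(self, rng):
        universe = [f"g{i}" for i in range(40)]
        sets = {
            n: set(rng.choice(universe, int(rng.integers(5, 30)), replace=False))
            for n in ("s1", "s2", "s3", "s4")
        }
        out = multiway_intersection(sets, min_sets=2).set_index("gene")
        for g in universe:
            count = sum(g in s for s in sets.values())
            if count >= 2:
                assert out.loc[g, "n_sets"] == count
            else:
                assert g not in out.index

    def test_fewer_than_two_sets_rejected(self):
        with pytest.raises(ValueError):
            multiway_intersection({"a": {"X"}})


def test_promoter_peak_genes_extracts_promoter_class():
    peaks = _peaks([("chr1", 9_900, 10_100), ("chr1", 49_900, 50_100)])
    out = annotate_peaks(peaks, TOY_ANN)
    assert promoter_peak_genes(out) == {"gA"}
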