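"""Enrichment arithmetic, population matrices, Ward clustering, correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from nfykit import synthetic
from nfykit.annotation import (
    AnnotationMap,
    assign_blocks,
    cluster,
    correlate,
    enrich,
    population_matrix,
)


@pytest.fixture
def toy_map():
    universe = {f"u{i}" for i in range(100)}
    terms = {
        "termA": {f"u{i}" for i in range(10)},
        "termB": {f"u{i}" for i in range(50, 70)},
    }
    return AnnotationMap(terms, universe)


def fisher_two_sided_oracle(k, n_list, K, N):
    """Two-sided Fisher p by full hypergeometric enumeration: sum the
    probabilities of all feasible tables no more likely than the observed."""
    lo, hi = max(0, n_list + K - N), min(n_list, K)
    pmf = {x: hypergeom.pmf(x, N, K, n_list) for x in range(lo, hi + 1)}
    p_obs = pmf[k]
    return sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-9))


class TestEnrich:
    def test_population_and_fold_arithmetic(self, toy_map):
        # k=5, n=10, K=10, N=100 -> population 50%, fold 5.0
        gene_list = {f"u{i}" for i in range(5)} | {f"u{i}" for i in range(90, 95)}
        rows = enrich(gene_list, toy_map)
        a = rows.loc["termA"]
        assert a["k"] == 5
        assert a["population_pct"] == pytest.approx(50.0)
        assert a["fold"] == pytest.approx(5.0)

    def test_fisher_matches_hypergeometric_enumeration(self, toy_map):
        gene_list = {f"u{i}" for i in range(5)} | {f"u{i}" for i in range(90, 95)}
        rows = enrich(gene_list, toy_map)
        for term in rows.index:
            r = rows.loc[term]
            oracle = fisher_two_sided_oracle(int(r["k"]), int(r["n_list"]), int(r["K"]), int(r["N"]))
            assert r["fisher_p"] == pytest.approx(oracle, abs=1e-12)

    def test_list_equals_universe_fold_one(self, toy_map):
        rows = enrich(set(toy_map.universe), toy_map)
        assert np.allclose(rows["fold"], 1.0)

    def test_fisher_invariant_under_simultaneous_swap(self):
        # swapping both rows and both columns of the 2x2 table keeps p
        from scipy.stats import fisher_exact

        k, n_list, K, N = 7, 30, 25, 200
        t = [[k, n_list - k], [K - k, N - K - n_list + k]]
        swapped = [[t[1][1], t[1][0]], [t[0][1], t[0][0]]]
        assert fisher_exact(t)[1] == pytest.approx(fisher_exact(swapped)[1], rel=1e-12)

    def test_stray_genes_warned_and_dropped(self, toy_map):
        with pytest.warns(UserWarning, match="outside the universe"):
            rows = enrich({"u0", "u1", "alien"}, toy_map)
        assert (rows["n_list"] == 2).all()

    def test_empty_list_rejected(self, toy_map):
        with pytest.raises(ValueError):
            enrich(set(), toy_map)


class TestPopulationMatrix:
    def test_identical_lists_identical_columns(self, toy_map):
        genes = {f"u{i}" for i in range(20)}
        pm = population_matrix({"a": genes, "b": genes}, toy_map)
        assert (pm["a"] == pm["b"]).all()

    def test_unannotated_list_all_zero_column(self, toy_map):
        pm = population_matrix(
            {"a": {f"u{i}" for i in range(5)}, "b": {f"u{i}" for i in range(80, 90)}},
            toy_map,
        )
        assert (pm["b"] == 0).all()
        assert pm.to_numpy().min() >= 0 and pm.to_numpy().max() <= 100

    def test_skew_profiles_order_block2_columns(self):
        amap, g_er, _ = synthetic.gen_annotation(40, 2000, "ER-skew", 300, seed=1, map_seed=50)
        _, g_cc, _ = synthetic.gen_annotation(40, 2000, "cellcycle-skew", 300, seed=2, map_seed=50)
        pm = population_matrix({"er": g_er, "cc": g_cc}, amap)
        block2 = [t for t, b in amap.blocks.items() if b == "CL2"]
        assert pm.loc[block2, "er"].mean() > pm.loc[block2, "cc"].mean()


class TestCorrelate:
    def test_positive_affine_r_one(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 5.0, 7.0]})
        m["b"] = 2 * m["a"] + 1
        assert correlate(m, "a", "b").r == pytest.approx(1.0)

    def test_negation_r_minus_one(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 5.0]})
        m["b"] = -m["a"]
        assert correlate(m, "a", "b").r == pytest.approx(-1.0)

    def test_self_correlation_exactly_one(self):
        m = pd.DataFrame({"a": [3.0, 1.0, 4.0, 1.0, 5.0]})
        m["b"] = m["a"]
        assert correlate(m, "a", "b").r == 1.0

    def test_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame({"a": rng.normal(size=50), "b": rng.normal(size=50)})
        a, b = m["a"].to_numpy(), m["b"].to_numpy()
        oracle = ((a - a.mean()) * (b - b.mean())).sum() / np.sqrt(
            ((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum()
        )
        assert correlate(m, "a", "b").r == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_rejected(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="variance"):
            correlate(m, "a", "b")

    def test_too_few_rows_rejected(self):
        m = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(ValueError, match=">=3"):
            correlate(m, "a", "b")


class TestCluster:
    def test_duplicated_columns_merge_first_at_zero(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=10)
        m = pd.DataFrame(
            {"a": base, "b": base, "c": base + 10, "d": base - 10}
        )
        dend = cluster(m, axis="lists")
        first = dend.linkage[0]
        assert first[2] == 0.0  # height of the first merge
        merged = {dend.labels[int(first[0])], dend.labels[int(first[1])]}
        assert merged == {"a", "b"}

    def test_two_separated_pairs_merge_within_pairs_first(self):
        rng = np.random.default_rng(5)
        base1, base2 = rng.normal(size=10), rng.normal(size=10) + 50
        m = pd.DataFrame(
            {
                "a1": base1 + rng.normal(0, 0.1, 10),
                "a2": base1 + rng.normal(0, 0.1, 10),
                "b1": base2 + rng.normal(0, 0.1, 10),
                "b2": base2 + rng.normal(0, 0.1, 10),
            }
        )
        dend = cluster(m, axis="lists")
        first_two = [
            {dend.labels[int(row[0])], dend.labels[int(row[1])]}
            for row in dend.linkage[:2]
            if row[0] < 4 and row[1] < 4
        ]
        assert {"a1", "a2"} in first_two
        assert {"b1", "b2"} in first_two

    def test_heights_nondecreasing_and_permutation_invariant(self):
        rng = np.random.default_rng(6)
        m = pd.DataFrame(rng.normal(size=(12, 5)), columns=list("abcde"))
        dend = cluster(m, axis="lists")
        assert (np.diff(dend.linkage[:, 2]) >= -1e-9).all()
        perm = m[["d", "b", "a", "e", "c"]]
        dend2 = cluster(perm, axis="lists")
        # same partition at every cut despite column permutation
        for k in range(1, 6):
            c1, c2 = dend.cut(k), dend2.cut(k)
            part1 = {frozenset(l for l, c in c1.items() if c == i) for i in set(c1.values())}
            part2 = {frozenset(l for l, c in c2.items() if c == i) for i in set(c2.values())}
            assert part1 == part2

    def test_profile_groups_separate_at_two_cluster_cut(self):
        hits = 0
        for seed in range(5):
            lists = {}
            amap = None
            for i, (cell, profile) in enumerate(
                [("N2a", "ER-skew"), ("striatum", "ER-skew"),
                 ("HeLa", "cellcycle-skew"), ("ES", "cellcycle-skew")]
            ):
                amap, glist, _ = synthetic.gen_annotation(
                    40, 2000, profile, 300, seed=100 * seed + i, map_seed=seed
                )
                lists[cell] = glist
            pm = population_matrix(lists, amap)
            cut = cluster(pm, axis="lists").cut(2)
            if cut["N2a"] == cut["striatum"] and cut["HeLa"] == cut["ES"] and cut["N2a"] != cut["HeLa"]:
                hits += 1
        assert hits >= 4

    def test_nan_rejected(self):
        m = pd.DataFrame({"a": [1.0, np.nan], "b": [2.0, 3.0]})
        with pytest.raises(ValueError, match="NaN"):
            cluster(m, axis="lists")


class TestAssignBlocks:
    def test_singletons_and_single_block(self):
        rng = np.random.default_rng(7)
        m = pd.DataFrame(rng.normal(size=(6, 4)))
        m.index = [f"t{i}" for i in range(6)]
        dend = cluster(m, axis="terms")
        singletons = assign_blocks(dend, n_clusters=6)
        assert len(set(singletons.values())) == 6
        one = assign_blocks(dend, n_clusters=1)
        assert set(one.values()) == {1}

    def test_four_block_structure_recovered(self):
        # four well-separated centroids, three terms each
        rng = np.random.default_rng(8)
        rows, truth = {}, {}
        for b in range(4):
            centroid = rng.normal(scale=0.5, size=5) + 20 * b
            for j in range(3):
                name = f"t{b}{j}"
                rows[name] = centroid + rng.normal(0, 0.1, 5)
                truth[name] = b
        m = pd.DataFrame(rows).T
        blocks = assign_blocks(cluster(m, axis="terms"), n_clusters=4)
        # partition identical to truth (labels may differ)
        mapping = {}
        for term, b in blocks.items():
            mapping.setdefault(b, set()).add(truth[term])
        assert all(len(v) == 1 for v in mapping.values())
        assert len(mapping) == 4

    def test_block_ids_stable_by_leaf_order(self):
        rng = np.random.default_rng(9)
        m = pd.DataFrame(rng.normal(size=(8, 3)), index=[f"t{i}" for i in range(8)])
        dend = cluster(m, axis="terms")
        blocks = assign_blocks(dend, n_clusters=3)
        seen = []
        for leaf in dend.leaf_order():
            if blocks[leaf] not in seen:
                seen.append(blocks[leaf])
        assert seen == [1, 2, 3]


class TestFormats:
    def test_gmt_round_trip(self, tmp_path, toy_map):
        toy_map.blocks = {"termA": "CL1", "termB": "CL2"}
        path = tmp_path / "ann.gmt"
        toy_map.to_gmt(path)
        back = AnnotationMap.from_gmt(path, universe=toy_map.universe)
        assert back.terms == toy_map.terms
        assert back.blocks == toy_map.blocks

    def test_newick_export_parses(self, tmp_path):
        from io import StringIO

        from Bio import Phylo

        rng = np.random.default_rng(10)
        m = pd.DataFrame(rng.normal(size=(5, 4)), columns=list("wxyz"))
        dend = cluster(m, axis="lists")
        tree = Phylo.read(StringIO(dend.to_newick()), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == list("wxyz")
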