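import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import pdist, squareform

from conftest import make_de_table
from synarray.interaction import (
    classify_all,
    classify_group1,
    classify_group2,
    classify_group3,
    cluster_group1,
    venn_counts,
)

C = ("NF_vs_CT", "NAA_vs_CT", "NFNAA_vs_CT", "NFNAA_vs_NAA")


def tables_from_sets(universe, nf, naa, nfnaa, nfnaa_naa=(), lfcs=None):
    """Build four DE tables from DEG membership sets (lfc defaults +1)."""
    lfcs = lfcs or {}
    out = {}
    for cid, members in zip(C, (nf, naa, nfnaa, nfnaa_naa)):
        entries = {}
        for g in universe:
            lfc = lfcs.get((cid, g), 1.0 if g in members else 0.0)
            call = ("up" if lfc > 0 else "down") if g in members else "ns"
            entries[g] = (lfc, call)
        out[cid] = make_de_table(entries)
    return out


class TestVenn:
    def test_disjoint_sets(self):
        u = [f"g{i}" for i in range(20)]
        t = tables_from_sets(u, set(u[:2]), set(u[2:5]), set(u[5:9]))
        v = venn_counts(t)
        assert v["NF_only"] == 2 and v["NAA_only"] == 3 and v["NFNAA_only"] == 4
        assert v["all_three"] == 0 and v["union"] == 9

    def test_identical_sets(self):
        u = [f"g{i}" for i in range(10)]
        s = set(u[:5])
        v = venn_counts(tables_from_sets(u, s, s, s))
        assert v["all_three"] == 5
        assert v["NF_only"] == v["NAA_only"] == v["NFNAA_only"] == 0

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(31)
        u = [f"g{i}" for i in range(1000)]
        sets = [set(np.array(u)[rng.random(1000) < p]) for p in (0.2, 0.4, 0.3)]
        v = venn_counts(tables_from_sets(u, *sets))
        # brute force: walk every gene and tally its membership pattern
        regions = {k: 0 for k in (
            "NF_only", "NAA_only", "NFNAA_only", "NF_and_NAA",
            "NF_and_NFNAA", "NAA_and_NFNAA", "all_three")}
        names = {
            (True, False, False): "NF_only",
            (False, True, False): "NAA_only",
            (False, False, True): "NFNAA_only",
            (True, True, False): "NF_and_NAA",
            (True, False, True): "NF_and_NFNAA",
            (False, True, True): "NAA_and_NFNAA",
            (True, True, True): "all_three",
        }
        for g in u:
            pattern = tuple(g in s for s in sets)
            if any(pattern):
                regions[names[pattern]] += 1
        for k, n in regions.items():
            assert v[k] == n
        assert v["union"] == sum(regions.values())


class TestGroup1:
    def test_only_combined_responders_kept(self):
        u = ["a", "b", "c"]
        t = tables_from_sets(
            u, nf=set(), naa={"b"}, nfnaa={"a", "b"},
            lfcs={("NFNAA_vs_CT", "a"): 2.0},
        )
        up, down = classify_group1(t)
        assert up == ["a"] and down == []

    def test_direction_from_combined_contrast(self):
        u = ["a", "b"]
        t = tables_from_sets(
            u, nf=set(), naa=set(), nfnaa={"a", "b"},
            lfcs={("NFNAA_vs_CT", "a"): 1.2, ("NFNAA_vs_CT", "b"): -0.9},
        )
        up, down = classify_group1(t)
        assert up == ["a"] and down == ["b"]


class TestGroup2:
    def base_tables(self, lfc_naa, lfc_nfnaa):
        u = ["a"]
        return tables_from_sets(
            u, nf=set(), naa={"a"}, nfnaa={"a"}, nfnaa_naa={"a"},
            lfcs={("NAA_vs_CT", "a"): lfc_naa, ("NFNAA_vs_CT", "a"): lfc_nfnaa},
        )

    @pytest.mark.parametrize(
        "lfc_naa,lfc_nfnaa,sublabel",
        [
            (1.0, 1.8, "enhanced"),
            (-2.0, -1.0, "antagonized"),
            (1.0, -1.2, "antagonized"),  # sign reversal
            (-1.0, -1.8, "enhanced"),
        ],
    )
    def test_sublabel_rule(self, lfc_naa, lfc_nfnaa, sublabel):
        g2 = classify_group2(self.base_tables(lfc_naa, lfc_nfnaa))
        assert g2.loc["a", "sublabel"] == sublabel

    def test_nf_responders_excluded(self):
        u = ["a"]
        t = tables_from_sets(u, nf={"a"}, naa={"a"}, nfnaa={"a"}, nfnaa_naa={"a"})
        assert len(classify_group2(t)) == 0

    def test_requires_direct_contrast(self):
        u = ["a"]
        t = tables_from_sets(u, nf=set(), naa={"a"}, nfnaa={"a"}, nfnaa_naa=set())
        assert len(classify_group2(t)) == 0


class TestGroup3:
    def base_tables(self, lfc_nf, lfc_nfnaa):
        u = ["a"]
        return tables_from_sets(
            u, nf={"a"}, naa=set(), nfnaa={"a"},
            lfcs={("NF_vs_CT", "a"): lfc_nf, ("NFNAA_vs_CT", "a"): lfc_nfnaa},
        )

    def test_hand_arithmetic_on_linear_scale(self):
        # FC_NF = 2, FC_NFNAA = 2**0.4 ~ 1.32: relative difference ~ 0.34
        cand, g3 = classify_group3(self.base_tables(1.0, 0.4))
        assert cand == ["a"] and g3 == ["a"]
        rel = abs(2**0.4 - 2.0) / 2.0
        assert rel == pytest.approx(0.3402, abs=1e-4)

    def test_equal_responses_stay_candidates(self):
        cand, g3 = classify_group3(self.base_tables(1.0, 1.0))
        assert cand == ["a"] and g3 == []

    def test_zero_threshold_keeps_all_candidates(self):
        cand, g3 = classify_group3(self.base_tables(1.0, 1.0), rel_threshold=0.0)
        assert g3 == cand

    def test_log_scale_option(self):
        # |0.8 - 1.0| / 1.0 = 0.2 < 0.3 on log scale, but the linear rule
        # gives |2**0.8 - 2| / 2 ~ 0.13 < 0.3 too; use a wider gap
        cand, g3_lin = classify_group3(self.base_tables(1.0, 0.65))
        _, g3_log = classify_group3(self.base_tables(1.0, 0.65), scale="log")
        assert g3_log == ["a"]  # |0.65-1|/1 = 0.35 >= 0.3
        assert g3_lin == []  # |2**0.65 - 2|/2 = 0.22 < 0.3


class TestClusterGroup1:
    def test_identical_rows_adjacent(self):
        m = pd.DataFrame(
            [[1.0, 2.0, 0.5], [-1.0, -2.0, -0.5], [1.0, 2.0, 0.5]],
            index=["a", "b", "c"],
            columns=["NF", "NAA", "NFNAA"],
        )
        order, z = cluster_group1(m)
        ia, ic = order.index("a"), order.index("c")
        assert abs(ia - ic) == 1
        assert z[0, 2] == 0.0  # zero-distance merge happens first

    def test_permutation_invariant_topology(self):
        rng = np.random.default_rng(33)
        m = pd.DataFrame(
            rng.normal(size=(20, 3)),
            index=[f"g{i}" for i in range(20)],
            columns=["NF", "NAA", "NFNAA"],
        )
        _, z1 = cluster_group1(m)
        perm = m.sample(frac=1, random_state=2)
        _, z2 = cluster_group1(perm)
        # same merge heights and, via cophenetic distances mapped back to
        # gene labels, the same tree
        np.testing.assert_allclose(np.sort(z1[:, 2]), np.sort(z2[:, 2]))
        d1 = pd.DataFrame(
            squareform(cophenet(z1)), index=m.index, columns=m.index
        )
        d2 = pd.DataFrame(
            squareform(cophenet(z2)), index=perm.index, columns=perm.index
        )
        np.testing.assert_allclose(
            d1.to_numpy(), d2.loc[m.index, m.index].to_numpy(), atol=1e-12
        )

    def test_single_gene_trivial(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0]], index=["solo"])
        order, z = cluster_group1(m)
        assert order == ["solo"] and z is None

    def test_matches_naive_agglomerative_oracle(self):
        rng = np.random.default_rng(34)
        x = rng.normal(size=(50, 3))
        m = pd.DataFrame(x, index=[f"g{i}" for i in range(50)])
        _, z = cluster_group1(m)
        z_naive = naive_average_linkage(x)
        np.testing.assert_allclose(z[:, 2], z_naive[:, 2], rtol=1e-10)
        np.testing.assert_allclose(
            squareform(cophenet(z)), squareform(cophenet(z_naive)), rtol=1e-10
        )


def naive_average_linkage(x):
    """O(n^3) UPGMA on euclidean distances, emitting a scipy linkage matrix."""
    n = len(x)
    d = squareform(pdist(x))
    clusters = {i: [i] for i in range(n)}
    ids = {i: i for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            dist = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or dist < best[0]:
                best = (dist, a, b)
        dist, a, b = best
        merges.append(
            [min(ids[a], ids[b]), max(ids[a], ids[b]), dist,
             len(clusters[a]) + len(clusters[b])]
        )
        clusters[a] = clusters[a] + clusters.pop(b)
        ids[a] = next_id
        next_id += 1
    return np.array(merges)


class TestClassifyAll:
    def test_groups_disjoint_on_random_inputs(self):
        rng = np.random.default_rng(35)
        u = [f"g{i}" for i in range(300)]
        for _ in range(10):
            sets = [
                set(np.array(u)[rng.random(300) < p])
                for p in (0.1, 0.4, 0.45, 0.2)
            ]
            lfcs = {
                (cid, g): float(rng.normal(0, 1.5))
                for cid in C
                for g in u
            }
            tables = {}
            for cid, members in zip(C, sets):
                entries = {
                    g: (
                        lfcs[(cid, g)],
                        ("up" if lfcs[(cid, g)] > 0 else "down")
                        if g in members
                        else "ns",
                    )
                    for g in u
                }
                tables[cid] = make_de_table(entries)
            groups = classify_all(tables)  # asserts disjointness internally
            s = groups.summary()
            assert s["group1"] == s["group1_up"] + s["group1_down"]
            assert s["group3"] <= s["group3_candidates"]

    def test_group_sizes_monotone_in_thresholds(self, noisy_run):
        from synarray.diffexpr import call_degs

        de = noisy_run["de"]
        sizes = []
        for lfc_min in (0.5, 0.75, 1.0, 1.25):
            recalled = {
                cid: call_degs(t, alpha=0.05, lfc_min=lfc_min)
                for cid, t in de.items()
            }
            sizes.append(len(venn_counts(recalled)) and venn_counts(recalled)["union"])
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))
        alphas = []
        for alpha in (0.05, 0.01, 0.001):
            recalled = {
                cid: call_degs(t, alpha=alpha, lfc_min=0.75)
                for cid, t in de.items()
            }
            alphas.append(venn_counts(recalled)["union"])
        assert all(a >= b for a, b in zip(alphas, alphas[1:]))
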