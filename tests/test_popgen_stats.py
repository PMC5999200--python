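import itertools

import numpy as np
import pandas as pd
import pytest

from gsikit.genotype_io import BaselineCollection, table_from_records
from gsikit.popgen_stats import (
    allele_counts,
    cse_chord_distance,
    heterozygosity,
    hwe_exact_test,
    hwe_tests,
    nj_tree,
    pairwise_fst,
)
from gsikit.synthetic_data import SimConfig, generate_baseline


def _single_pop(records, loci):
    t = table_from_records(records, loci=loci, labels=["P"] * len(records))
    return BaselineCollection(t, ["P"], {"P": "P"})


class TestHeterozygosity:
    def test_monomorphic_locus_zero(self):
        b = _single_pop({"f1": [("1", "1")], "f2": [("1", "1")]}, ["L"])
        het = heterozygosity(allele_counts(b))
        assert het.h_o_overall == 0.0 and het.h_e_overall == 0.0

    def test_hand_example_four_diploids(self):
        # allele counts (6,2), two observed heterozygotes:
        # H_O = 2/4; H_E = (8/7)(1 - 0.75^2 - 0.25^2)
        b = _single_pop(
            {
                "f1": [("a", "a")],
                "f2": [("a", "a")],
                "f3": [("a", "b")],
                "f4": [("a", "b")],
            },
            ["L"],
        )
        het = heterozygosity(allele_counts(b))
        assert het.h_o_overall == pytest.approx(0.5)
        assert het.h_e_overall == pytest.approx((8 / 7) * (1 - 0.75**2 - 0.25**2))

    def test_balanced_biallelic_large_n_limit(self):
        recs = {f"f{i}": [("a", "b")] for i in range(500)}
        b = _single_pop(recs, ["L"])
        het = heterozygosity(allele_counts(b))
        assert het.h_e_overall == pytest.approx(0.5, abs=1e-3)

    def test_empty_locus_excluded(self):
        b = _single_pop({"f1": [("a", "b"), None], "f2": [("a", "a"), None]}, ["L0", "L1"])
        het = heterozygosity(allele_counts(b))
        assert het.excluded_loci == ["L1"]
        assert not np.isnan(het.h_o_overall)


class TestHwe:
    def test_enumeration_oracle_all_het(self):
        """Permutation p matches full enumeration of the 945 pairings of
        10 gene copies (5 a, 5 b) when all 5 diploids are heterozygous."""
        a = np.zeros(5, dtype=int)
        b = np.ones(5, dtype=int)

        copies = [0] * 5 + [1] * 5

        def matchings(items):
            if not items:
                yield []
                return
            first, rest = items[0], items[1:]
            seen = set()
            for k, other in enumerate(rest):
                if other in seen:
                    continue
                seen.add(other)
                for m in matchings(rest[:k] + rest[k + 1 :]):
                    yield [(first, other)] + m

        def stat(pairs):
            h = sum(1 for x, y in pairs if x != y)
            counts = {}
            for x, y in pairs:
                g = (min(x, y), max(x, y))
                counts[g] = counts.get(g, 0) + 1
            logfact = sum(sum(np.log(np.arange(1, c + 1))) for c in counts.values())
            return h * np.log(2.0) - logfact

        stats_all = [stat(m) for m in matchings(copies)]
        t_obs = stat(list(zip(a, b)))
        less = sum(1 for t in stats_all if t < t_obs - 1e-12)
        ties = sum(1 for t in stats_all if abs(t - t_obs) <= 1e-12)
        p_exact = (less + 0.5 * ties) / len(stats_all)

        n_perm = 40000
        p_mc, _ = hwe_exact_test(a, b, n_perm=n_perm, seed=5)
        se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(p_mc - p_exact) < 4 * se + 1.0 / n_perm

    def test_monomorphic_cells_untestable(self):
        recs = {
            "f1": [("1", "1"), ("1", "2")],
            "f2": [("1", "1"), ("2", "2")],
            "f3": [("1", "1"), ("1", "1")],
        }
        b = _single_pop(recs, ["Lmono", "Lpoly"])
        rep = hwe_tests(b, n_perm=200, seed=1)
        assert rep.n_tests == 1
        assert np.isnan(rep.p[0, 0]) and not np.isnan(rep.p[0, 1])
        assert rep.bonferroni_alpha == pytest.approx(0.05 / 1)

    def test_n_perm_floor(self):
        b = _single_pop({"f1": [("1", "2")], "f2": [("1", "1")]}, ["L"])
        with pytest.raises(ValueError):
            hwe_tests(b, n_perm=50)


def _two_pop_counts(recs_a, recs_b, loci):
    recs = {}
    labels = []
    for k, v in recs_a.items():
        recs["A" + k] = v
        labels.append("A")
    for k, v in recs_b.items():
        recs["B" + k] = v
        labels.append("B")
    t = table_from_records(recs, loci=loci, labels=labels)
    return allele_counts(BaselineCollection(t, ["A", "B"], {"A": "A", "B": "B"}))


class TestWeirCockerham:
    def _toy_counts(self):
        # pop1: allele counts (8,2), 2 hets; pop2: (3,7), 3 hets; 5 diploids each
        pop1 = {f"{i}": [("a", "a")] for i in range(3)}
        pop1.update({f"h{i}": [("a", "b")] for i in range(2)})
        pop2 = {f"{i}": [("b", "b")] for i in range(2)}
        pop2.update({f"h{i}": [("a", "b")] for i in range(3)})
        return _two_pop_counts(pop1, pop2, ["L"])

    @staticmethod
    def _wc_biallelic(n, p, h):
        """Independent direct transcription of the 1984 variance components."""
        n = np.asarray(n, float)
        p = np.asarray(p, float)
        h = np.asarray(h, float)
        r = len(n)
        nbar = n.mean()
        nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
        pbar = (n * p).sum() / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n * h).sum() / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        return a, b, c

    def test_toy_matches_hand_computation(self):
        counts = self._toy_counts()
        fst, per_locus = pairwise_fst(counts)
        num = den = 0.0
        for p, h in [((0.8, 0.3), (0.4, 0.6)), ((0.2, 0.7), (0.4, 0.6))]:
            a, b, c = self._wc_biallelic([5, 5], p, h)
            num += a
            den += a + b + c
        assert fst.loc["A", "B"] == pytest.approx(num / den, abs=1e-12)
        assert per_locus["L"] == pytest.approx(num / den, abs=1e-12)

    def test_identical_counts_near_zero(self):
        recs = {f"{i}": [("a", "b")] for i in range(5)}
        recs.update({f"x{i}": [("a", "a")] for i in range(5)})
        counts = _two_pop_counts(recs, dict(recs), ["L"])
        fst, _ = pairwise_fst(counts)
        assert fst.loc["A", "B"] < 0.01  # may be slightly negative

    def test_fixed_difference_is_one(self):
        pa = {f"{i}": [("a", "a")] for i in range(8)}
        pb = {f"{i}": [("b", "b")] for i in range(8)}
        fst, _ = pairwise_fst(_two_pop_counts(pa, pb, ["L"]))
        assert fst.loc["A", "B"] == pytest.approx(1.0)

    def test_invariant_to_allele_relabeling_and_pop_order(self):
        counts = self._toy_counts()
        fst, _ = pairwise_fst(counts)
        pop1 = {f"{i}": [("z", "z")] for i in range(3)}
        pop1.update({f"h{i}": [("q", "z")] for i in range(2)})
        pop2 = {f"{i}": [("q", "q")] for i in range(2)}
        pop2.update({f"h{i}": [("q", "z")] for i in range(3)})
        relabeled = _two_pop_counts(pop2, pop1, ["L"])  # pops swapped too
        fst2, _ = pairwise_fst(relabeled)
        assert fst.loc["A", "B"] == pytest.approx(fst2.loc["A", "B"], abs=1e-12)


class TestChordDistance:
    def test_identical_frequencies_zero(self):
        recs = {f"{i}": [("a", "b")] for i in range(4)}
        counts = _two_pop_counts(recs, dict(recs), ["L"])
        d = cse_chord_distance(counts)
        assert d.loc["A", "B"] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_alleles_distance_one(self):
        pa = {f"{i}": [("a", "a"), ("c", "c")] for i in range(4)}
        pb = {f"{i}": [("b", "b"), ("d", "d")] for i in range(4)}
        d = cse_chord_distance(_two_pop_counts(pa, pb, ["L1", "L2"]))
        assert d.loc["A", "B"] == pytest.approx(1.0)

    def test_one_locus_hand_value(self):
        # p=(1,0) vs q=(0.5,0.5): d = sqrt(1 - sqrt(0.5))
        pa = {f"{i}": [("a", "a")] for i in range(6)}
        pb = {"0": [("a", "a")], "1": [("b", "b")], "2": [("a", "b")], "3": [("a", "b")]}
        d = cse_chord_distance(_two_pop_counts(pa, pb, ["L"]))
        assert d.loc["A", "B"] == pytest.approx(np.sqrt(1 - np.sqrt(0.5)), abs=1e-12)

    def test_symmetry_zero_diagonal(self, synth_small):
        counts = allele_counts(synth_small.baseline)
        d = cse_chord_distance(counts)
        arr = d.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 0)


class TestNjTree:
    def test_additive_four_taxon_recovery(self):
        # tree ((A:2,B:3):1,C:4,D:5) -> additive distances
        names = ["A", "B", "C", "D"]
        dist = {
            ("A", "B"): 5, ("A", "C"): 7, ("A", "D"): 8,
            ("B", "C"): 8, ("B", "D"): 9, ("C", "D"): 9,
        }
        m = np.zeros((4, 4))
        for (x, y), v in dist.items():
            i, j = names.index(x), names.index(y)
            m[i, j] = m[j, i] = v
        tree, _ = nj_tree(pd.DataFrame(m, index=names, columns=names))
        tt = tree.tip_tip_distances()
        ids = list(tt.ids)
        for (x, y), v in dist.items():
            assert tt[ids.index(x), ids.index(y)] == pytest.approx(v, abs=1e-9)

    def test_three_taxa_three_point_formulas(self):
        names = ["A", "B", "C"]
        m = np.array([[0, 5, 7], [5, 0, 8], [7, 8, 0]], dtype=float)
        tree, _ = nj_tree(pd.DataFrame(m, index=names, columns=names))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx((5 + 7 - 8) / 2)
        assert lengths["B"] == pytest.approx((5 + 8 - 7) / 2)
        assert lengths["C"] == pytest.approx((7 + 8 - 5) / 2)

    def test_asymmetric_matrix_rejected(self):
        m = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(pd.DataFrame(m, index=["A", "B"], columns=["A", "B"]))

    def test_regional_clusters_get_bootstrap_support(self):
        groups = [[0, 1, 2], [3, 4, 5], [6, 7, 8]]
        sb = generate_baseline(
            SimConfig(
                n_pops=9, n_loci=30, mean_alleles_per_locus=6, fst_target=0.02,
                n_per_pop=30, missing_rate=0.0, error_rate=0.0, n_duplicates=0,
                hierarchical_groups=(groups, 0.12), seed=7,
            )
        )
        counts = allele_counts(sb.baseline)
        chord = cse_chord_distance(counts)
        tree, newick = nj_tree(chord, counts=counts, n_boot=60, seed=8)
        pops = sb.baseline.collections
        all_tips = frozenset(pops)
        ref = min(all_tips)
        supported = {}
        for node in tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if ref in side:
                side = all_tips - side
            if node.name is not None:
                supported[side] = float(node.name)
        for g in groups:
            side = frozenset(pops[i] for i in g)
            if ref in side:
                side = all_tips - side
            assert supported.get(side, 0.0) >= 50.0

    def test_bipartitions_invariant_to_label_order(self, synth_small):
        counts = allele_counts(synth_small.baseline)
        d = cse_chord_distance(counts)
        perm = list(reversed(d.index))
        d2 = d.loc[perm, perm]
        t1, _ = nj_tree(d)
        t2, _ = nj_tree(d2)

        def parts(tree, tips):
            ref = min(tips)
            out = set()
            for node in tree.non_tips(include_self=False):
                side = frozenset(x.name for x in node.tips())
                if ref in side:
                    side = tips - side
                if 2 <= len(side) <= len(tips) - 2:
                    out.add(side)
            return out

        tips = frozenset(d.index)
        assert parts(t1, tips) == parts(t2, tips)
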