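"""Baseline summary statistics for multiallelic genotype data.

Covers the descriptive layer of a stock-identification baseline:
observed/expected heterozygosity, Monte Carlo exact Hardy-Weinberg
tests with Bonferroni correction, the Weir & Cockerham (1984) theta
estimator of F_ST (pairwise and per-locus), the Cavalli-Sforza &
Edwards chord distance, and a neighbor-joining tree with
locus-bootstrap support values.

Frequency-based statistics run off :class:`AlleleCountTable`, a dense
per-collection, per-locus allele-count summary; the Hardy-Weinberg
permutation test needs individual genotypes and takes the baseline
directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
import skbio
from skbio.tree import nj as _skbio_nj

from .genotype_io import AlleleIndex, BaselineCollection, build_allele_index

__all__ = [
    "AlleleCountTable",
    "HetReport",
    "HweReport",
    "allele_counts",
    "heterozygosity",
    "hwe_tests",
    "hwe_exact_test",
    "pairwise_fst",
    "cse_chord_distance",
    "nj_tree",
]


@dataclass
class AlleleCountTable:
    """Per-collection, per-locus allele counts.

    ``x[l]`` is a (C, A_l) integer array of gene-copy counts, ``n`` a
    (C, L) array of gene copies sampled (2 x non-missing individuals),
    ``het[l]`` a (C, A_l) array counting heterozygous individuals that
    carry each allele (needed by the Weir-Cockerham variance
    components), and ``n_ind`` the (C, L) non-missing individual count.
    """

    collections: list[str]
    loci: list[str]
    x: list[np.ndarray]
    n: np.ndarray
    het: list[np.ndarray]
    n_ind: np.ndarray
    index: AlleleIndex

    @property
    def n_collections(self) -> int:
        return len(self.collections)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def frequencies(self, l: int) -> np.ndarray:
        """(C, A_l) sample allele frequencies; rows with n=0 are NaN."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.x[l] / self.n[:, l][:, None]

    def pooled(self) -> "AlleleCountTable":
        """Collapse all collections into one (for panel-level QC stats)."""
        return AlleleCountTable(
            collections=["pooled"],
            loci=list(self.loci),
            x=[xl.sum(axis=0, keepdims=True) for xl in self.x],
            n=self.n.sum(axis=0, keepdims=True),
            het=[h.sum(axis=0, keepdims=True) for h in self.het],
            n_ind=self.n_ind.sum(axis=0, keepdims=True),
            index=self.index,
        )


def allele_counts(
    baseline: BaselineCollection, index: AlleleIndex | None = None
) -> AlleleCountTable:
    """Tally allele and heterozygote-carrier counts per collection x locus."""
    gt = baseline.genotypes
    if index is None:
        index = build_allele_index(gt)
    enc = index.encode(gt)
    C, L = len(baseline.collections), gt.n_loci
    col_of = {c: k for k, c in enumerate(baseline.collections)}
    ind_col = np.array([col_of[lab] for lab in gt.labels], dtype=int)
    A = index.n_alleles
    x = [np.zeros((C, A[l]), dtype=np.int64) for l in range(L)]
    het = [np.zeros((C, A[l]), dtype=np.int64) for l in range(L)]
    n = np.zeros((C, L), dtype=np.int64)
    n_ind = np.zeros((C, L), dtype=np.int64)
    for i in range(gt.n_individuals):
        c = ind_col[i]
        for l in range(L):
            a, b = enc[i, l]
            if a < 0:
                continue
            x[l][c, a] += 1
            x[l][c, b] += 1
            n[c, l] += 2
            n_ind[c, l] += 1
            if a != b:
                het[l][c, a] += 1
                het[l][c, b] += 1
    return AlleleCountTable(list(baseline.collections), list(gt.loci), x, n, het, n_ind, index)


# ---------------------------------------------------------------------------
# heterozygosity
# ---------------------------------------------------------------------------

@dataclass
class HetReport:
    """Observed and Nei-unbiased expected heterozygosity.

    Per-cell matrices are (C, L) with NaN where a collection has no data
    at a locus; per-locus values average cells across collections and the
    overall values average across loci.
    """

    h_o_cell: np.ndarray
    h_e_cell: np.ndarray
    h_o_per_locus: np.ndarray
    h_e_per_locus: np.ndarray
    h_o_overall: float
    h_e_overall: float
    excluded_loci: list[str]


def heterozygosity(counts: AlleleCountTable) -> HetReport:
    C, L = counts.n_collections, counts.n_loci
    h_o = np.full((C, L), np.nan)
    h_e = np.full((C, L), np.nan)
    for l in range(L):
        n = counts.n[:, l].astype(float)
        ok = n > 0
        if not ok.any():
            continue
        p = counts.frequencies(l)
        # observed: heterozygous individuals / individuals (each het indiv
        # carries 2 distinct alleles, so carrier counts sum to 2 x n_het)
        n_het = counts.het[l].sum(axis=1) / 2.0
        h_o[ok, l] = n_het[ok] / counts.n_ind[ok, l]
        gene_div = 1.0 - np.nansum(p ** 2, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            unbiased = n / (n - 1.0) * gene_div
        one = n == 1  # single gene copy: no diversity estimate
        unbiased[one] = np.nan
        h_e[ok, l] = unbiased[ok]
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN locus columns
        h_o_locus = np.nanmean(h_o, axis=0)
        h_e_locus = np.nanmean(h_e, axis=0)
    excluded = [counts.loci[l] for l in range(L) if np.isnan(h_o_locus[l])]
    keep = ~np.isnan(h_o_locus)
    return HetReport(
        h_o_cell=h_o,
        h_e_cell=h_e,
        h_o_per_locus=h_o_locus,
        h_e_per_locus=h_e_locus,
        h_o_overall=float(np.nanmean(h_o_locus[keep])) if keep.any() else float("nan"),
        h_e_overall=float(np.nanmean(h_e_locus[keep])) if keep.any() else float("nan"),
        excluded_loci=excluded,
    )


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact tests (Monte Carlo permutation)
# ---------------------------------------------------------------------------

@dataclass
class HweReport:
    collections: list[str]
    loci: list[str]
    p: np.ndarray  # (C, L), NaN where untestable
    alpha: float
    n_tests: int
    bonferroni_alpha: float
    significant_raw: np.ndarray
    significant_bonferroni: np.ndarray

    @property
    def n_significant_raw(self) -> int:
        return int(np.nansum(self.significant_raw))

    @property
    def n_significant_bonferroni(self) -> int:
        return int(np.nansum(self.significant_bonferroni))


def _perm_hwe_pvalues(a: np.ndarray, b: np.ndarray, n_perm: int, rng) -> tuple[float, float]:
    """Monte Carlo exact HWE p-values for one sample of diploid genotypes.

    ``a``, ``b`` are integer allele codes per individual.  Gene copies are
    pooled and re-paired at random; the test statistic is the conditional
    probability of the genotype configuration given the allele counts
    (Guo & Thompson style), whose variable part is
    ``h*log(2) - sum_g log(n_g!)``.  Returns the two-sided exact p-value
    and the one-sided heterozygote-deficit p-value.

    Both use the mid-p convention (half the tie mass at the observed
    statistic), which keeps null p-values close to Uniform(0,1) despite
    the discreteness of the statistic; the plain convention that counts
    the full tie mass is markedly conservative for multiallelic loci at
    realistic sample sizes.
    """
    n = a.size
    copies = np.concatenate([a, b])
    amax = int(copies.max()) + 1

    def _stat(lo: np.ndarray, hi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        het = (lo != hi).sum(axis=1)
        codes = np.minimum(lo, hi) * amax + np.maximum(lo, hi)
        s = np.sort(codes, axis=1)
        idx = np.arange(n)
        new = np.ones_like(s, dtype=bool)
        new[:, 1:] = s[:, 1:] != s[:, :-1]
        start = np.where(new, idx, 0)
        start = np.maximum.accumulate(start, axis=1)
        # within-run 1-based rank: sum of its logs = sum_g log(n_g!)
        log_fact = np.log(idx - start + 1.0).sum(axis=1)
        return het * np.log(2.0) - log_fact, het

    t_obs, h_obs = _stat(a[None, :], b[None, :])
    perms = rng.permuted(np.broadcast_to(copies, (n_perm, 2 * n)), axis=1)
    t_perm, h_perm = _stat(perms[:, 0::2], perms[:, 1::2])

    def _mid_p(values: np.ndarray, obs: float) -> float:
        less = int((values < obs - 1e-12).sum())
        ties = int((np.abs(values - obs) <= 1e-12).sum())
        return (less + 0.5 * (1 + ties)) / (n_perm + 1)

    return _mid_p(t_perm, t_obs[0]), _mid_p(h_perm.astype(float), float(h_obs[0]))


def hwe_tests(
    baseline: BaselineCollection,
    n_perm: int = 10000,
    seed: int | None = None,
    alpha: float = 0.05,
    index: AlleleIndex | None = None,
) -> HweReport:
    """Exact Hardy-Weinberg tests for every collection x locus cell.

    Cells monomorphic within the collection, or with fewer than 2 typed
    individuals, are untestable and excluded from the Bonferroni count.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    gt = baseline.genotypes
    if index is None:
        index = build_allele_index(gt)
    enc = index.encode(gt)
    rng = np.random.default_rng(seed)
    C, L = len(baseline.collections), gt.n_loci
    col_of = {c: k for k, c in enumerate(baseline.collections)}
    ind_col = np.array([col_of[lab] for lab in gt.labels], dtype=int)
    p = np.full((C, L), np.nan)
    for c in range(C):
        rows = np.where(ind_col == c)[0]
        for l in range(L):
            sub = enc[rows, l, :]
            sub = sub[sub[:, 0] >= 0]
            if sub.shape[0] < 2 or np.unique(sub).size < 2:
                continue
            p[c, l], _ = _perm_hwe_pvalues(sub[:, 0], sub[:, 1], n_perm, rng)
    testable = ~np.isnan(p)
    n_tests = int(testable.sum())
    bonf = alpha / n_tests if n_tests else float("nan")
    return HweReport(
        collections=list(baseline.collections),
        loci=list(gt.loci),
        p=p,
        alpha=alpha,
        n_tests=n_tests,
        bonferroni_alpha=bonf,
        significant_raw=np.where(testable, p < alpha, np.nan),
        significant_bonferroni=np.where(testable, p < bonf, np.nan),
    )


def hwe_exact_test(
    a: np.ndarray, b: np.ndarray, n_perm: int = 10000, seed: int | None = None
) -> tuple[float, float]:
    """Single-sample HWE test; returns (two-sided p, heterozygote-deficit p)."""
    rng = np.random.default_rng(seed)
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    if a.size < 2 or np.unique(np.concatenate([a, b])).size < 2:
        return float("nan"), float("nan")
    return _perm_hwe_pvalues(a, b, n_perm, rng)


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) theta
# ---------------------------------------------------------------------------

def _wc_components(counts: AlleleCountTable, pops: np.ndarray, l: int):
    """Per-allele variance components (a, b, c) at locus ``l`` over ``pops``.

    Returns three arrays of length A_l, or None if fewer than 2
    populations have data at the locus.
    """
    n_i = counts.n_ind[pops, l].astype(float)
    use = n_i > 0
    if use.sum() < 2:
        return None
    n_i = n_i[use]
    sub = pops[use]
    r = float(len(sub))
    p_i = counts.x[l][sub] / (2.0 * n_i[:, None])
    h_i = counts.het[l][sub] / n_i[:, None]
    n_bar = n_i.mean()
    if n_bar <= 1.0:
        return None
    n_c = (r * n_bar - (n_i ** 2).sum() / (r * n_bar)) / (r - 1.0)
    if n_c <= 0:
        return None
    p_bar = (n_i[:, None] * p_i).sum(axis=0) / (r * n_bar)
    s2 = (n_i[:, None] * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1.0) * n_bar)
    h_bar = (n_i[:, None] * h_i).sum(axis=0) / (r * n_bar)
    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - (r - 1.0) / r * s2 - h_bar / 4.0) / (n_bar - 1.0)
    )
    b = (n_bar / (n_bar - 1.0)) * (
        p_bar * (1 - p_bar) - (r - 1.0) / r * s2 - (2.0 * n_bar - 1.0) / (4.0 * n_bar) * h_bar
    )
    c = h_bar / 2.0
    return a, b, c


def _theta_over_loci(counts: AlleleCountTable, pops: np.ndarray) -> float:
    num = den = 0.0
    any_locus = False
    for l in range(counts.n_loci):
        comp = _wc_components(counts, pops, l)
        if comp is None:
            continue
        any_locus = True
        a, b, c = comp
        num += a.sum()
        den += (a + b + c).sum()
    if not any_locus or den == 0.0:
        return float("nan")
    return num / den


def pairwise_fst(counts: AlleleCountTable) -> tuple[pd.DataFrame, pd.Series]:
    """Weir-Cockerham theta for every collection pair, plus per-locus theta.

    Multi-locus values combine variance components as a ratio of sums.
    Negative estimates are reported as computed (clamp only for display).
    Pairs with no co-typed polymorphic loci come back NaN.
    """
    C = counts.n_collections
    if C < 2:
        raise ValueError("pairwise theta needs at least 2 collections")
    d = np.zeros((C, C))
    for i in range(C):
        for j in range(i + 1, C):
            th = _theta_over_loci(counts, np.array([i, j]))
            d[i, j] = d[j, i] = th
    per_locus = pd.Series(
        [
            (lambda comp: float("nan") if comp is None or (comp[0] + comp[1] + comp[2]).sum() == 0
             else comp[0].sum() / (comp[0] + comp[1] + comp[2]).sum())(
                _wc_components(counts, np.arange(C), l)
            )
            for l in range(counts.n_loci)
        ],
        index=counts.loci,
        name="theta",
    )
    return pd.DataFrame(d, index=counts.collections, columns=counts.collections), per_locus


# ---------------------------------------------------------------------------
# Cavalli-Sforza & Edwards chord distance
# ---------------------------------------------------------------------------

def cse_chord_distance(counts: AlleleCountTable) -> pd.DataFrame:
    """Chord distance d(i,j) = sqrt(mean_l (1 - sum_a sqrt(p_i p_j))).

    The per-locus term is the squared chord (one minus the cosine of the
    angle between square-root frequency vectors); averaging over co-typed
    loci and taking the square root follows the PHYLIP/gendist
    convention, under which fully disjoint allele sets give distance 1.
    """
    C = counts.n_collections
    if C < 2:
        raise ValueError("chord distance needs at least 2 collections")
    typed = counts.n > 0  # (C, L)
    if not typed.any(axis=1).all():
        bad = [counts.collections[c] for c in range(C) if not typed[c].any()]
        raise ValueError(f"collection(s) with no data at any locus: {', '.join(bad)}")
    # cos_l[i, j] = sum_a sqrt(p_il_a * p_jl_a), per locus
    d = np.zeros((C, C))
    n_shared = np.zeros((C, C))
    acc = np.zeros((C, C))
    for l in range(counts.n_loci):
        p = counts.frequencies(l)
        sp = np.sqrt(np.where(np.isnan(p), 0.0, p))
        cos = sp @ sp.T
        share = np.outer(typed[:, l], typed[:, l])
        acc += np.where(share, 1.0 - cos, 0.0)
        n_shared += share
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.sqrt(np.clip(acc / n_shared, 0.0, None))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry against float noise
    return pd.DataFrame(d, index=counts.collections, columns=counts.collections)


# ---------------------------------------------------------------------------
# neighbor-joining with locus bootstrap
# ---------------------------------------------------------------------------

def _as_skbio_dm(dist: pd.DataFrame) -> skbio.DistanceMatrix:
    arr = np.asarray(dist, dtype=float)
    if not np.allclose(arr, arr.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    arr = (arr + arr.T) / 2.0
    np.fill_diagonal(arr, 0.0)
    return skbio.DistanceMatrix(arr, ids=[str(i) for i in dist.index])


def _bipartitions(tree, all_tips: frozenset) -> set[frozenset]:
    """Canonical non-trivial bipartitions (side not containing the ref tip)."""
    ref = min(all_tips)
    parts = set()
    for node in tree.non_tips(include_self=True):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = all_tips - side
        if 2 <= len(side) <= len(all_tips) - 2:
            parts.add(side)
    return parts


def nj_tree(
    dist: pd.DataFrame,
    counts: AlleleCountTable | None = None,
    n_boot: int = 0,
    seed: int | None = None,
    support_cutoff: float = 50.0,
):
    """Saitou-Nei neighbor joining, optionally with locus-bootstrap support.

    When ``counts`` is given and ``n_boot > 0``, loci are resampled with
    replacement, the chord distance recomputed, and each internal edge of
    the main tree labeled with the percentage of bootstrap trees
    containing its bipartition; supports below ``support_cutoff`` are
    omitted from the labels, following common practice for publication
    trees.

    Returns ``(tree, newick)`` where ``tree`` is a ``skbio.TreeNode``.
    """
    tree = _skbio_nj(_as_skbio_dm(dist))
    if counts is not None and n_boot > 0:
        rng = np.random.default_rng(seed)
        all_tips = frozenset(str(i) for i in dist.index)
        boot_counts: dict[frozenset, int] = {}
        L = counts.n_loci
        for _ in range(n_boot):
            pick = rng.integers(0, L, size=L)
            bcounts = AlleleCountTable(
                collections=list(counts.collections),
                loci=[counts.loci[k] for k in pick],
                x=[counts.x[k] for k in pick],
                n=counts.n[:, pick],
                het=[counts.het[k] for k in pick],
                n_ind=counts.n_ind[:, pick],
                index=counts.index,
            )
            btree = _skbio_nj(_as_skbio_dm(cse_chord_distance(bcounts)))
            for part in _bipartitions(btree, all_tips):
                boot_counts[part] = boot_counts.get(part, 0) + 1
        for node in tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            ref = min(all_tips)
            if ref in side:
                side = all_tips - side
            if not (2 <= len(side) <= len(all_tips) - 2):
                continue
            support = 100.0 * boot_counts.get(side, 0) / n_boot
            node.name = str(int(round(support))) if support >= support_cutoff else None
    newick = str(tree).strip()
    return tree, newick
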