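"""Decision support for lumping collections into reporting units.

Baseline collections that cannot be told apart genetically are pooled
into reporting units before mixture analysis.  In practice this is an
iterative, partly judgment-driven process; this module encodes the
evidence sources as an explicit, deterministic rule set — neighbor-
joining tree proximity, mutual mis-assignment, and small sample size —
so a proposed grouping is reproducible and auditable.  The output is a
proposal for human review, not a replacement for it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import BaselineCollection

__all__ = [
    "MergeProposal",
    "misassignment_matrix",
    "propose_merges",
    "apply_ru_map",
]


@dataclass
class MergeProposal:
    """Proposed unions of collections, each with its triggering evidence.

    ``unions`` are disjoint sets of collection names; ``evidence`` holds,
    per union, the list of (rule, detail) pairs that triggered it.  Rules
    are ``small-n`` (undersampled collection joined to its nearest tree
    neighbor) and ``mutual-misassignment`` (reciprocal confusion at or
    above the cutoff).
    """

    unions: list[frozenset]
    evidence: dict[frozenset, list[tuple[str, str]]]

    def as_records(self) -> list[dict]:
        return [
            {
                "members": sorted(u),
                "evidence": [{"rule": r, "detail": d} for r, d in self.evidence[u]],
            }
            for u in self.unions
        ]


def misassignment_matrix(
    loo_posteriors: pd.DataFrame, labels: list[str]
) -> pd.DataFrame:
    """Fraction of each collection's individuals whose top leave-one-out
    assignment lands in each collection.

    Rows index the true collection, columns the assigned one; each row
    sums to 1 and the diagonal is the per-collection self-assignment
    rate.  Assignment here is plain argmax (no threshold): the matrix
    describes where individuals *would* go, which is what the lumping
    decision needs.
    """
    cols = list(loo_posteriors.columns)
    top = loo_posteriors.to_numpy().argmax(axis=1)
    m = pd.DataFrame(0.0, index=cols, columns=cols)
    sizes = {c: 0 for c in cols}
    for lab, t in zip(labels, top):
        m.loc[lab, cols[t]] += 1.0
        sizes[lab] += 1
    for c in cols:
        if sizes[c]:
            m.loc[c] /= sizes[c]
    return m


def _tip_distances(tree) -> pd.DataFrame:
    dm = tree.tip_tip_distances()
    ids = list(dm.ids)
    return pd.DataFrame(dm.data, index=ids, columns=ids)


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def propose_merges(
    tree,
    mis: pd.DataFrame,
    sizes: dict[str, int] | None = None,
    min_n: int = 30,
    mutual_cutoff: float = 0.20,
) -> MergeProposal:
    """Deterministic merge proposal from tree, mis-assignments, and sizes.

    Rules, applied in order and then transitively closed:

    1. every collection with fewer than ``min_n`` individuals is unioned
       with its nearest neighbor on the tree (ties to the first label in
       matrix order);
    2. every pair with reciprocal mis-assignment at or above
       ``mutual_cutoff`` in both directions is unioned.

    ``tree`` is a ``skbio.TreeNode`` whose tips are the collection
    names.  When ``sizes`` is None rule 1 is skipped.
    """
    if not 0.0 <= mutual_cutoff <= 1.0:
        raise ValueError("mutual_cutoff must be in [0, 1]")
    if min_n < 0:
        raise ValueError("min_n must be >= 0")
    cols = list(mis.index)
    if list(mis.columns) != cols:
        raise ValueError("mis-assignment matrix must be square with matching labels")
    uf = _UnionFind(cols)
    evidence_raw: list[tuple[str, str, str, str]] = []  # (a, b, rule, detail)

    small = [c for c in cols if sizes is not None and sizes.get(c, 0) < min_n]
    if small:
        if len(cols) == 2:
            td = pd.DataFrame(
                [[0.0, 1.0], [1.0, 0.0]], index=cols, columns=cols
            )  # only one possible neighbor
        else:
            td = _tip_distances(tree)
            if set(td.index) != set(cols):
                raise ValueError("tree tips and matrix labels differ")
        for c in small:
            d = td.loc[c].drop(index=c)
            # ties broken by matrix order for determinism
            nearest = min(
                (other for other in cols if other != c),
                key=lambda o: (d[o], cols.index(o)),
            )
            uf.union(c, nearest)
            evidence_raw.append(
                (c, nearest, "small-n", f"n={sizes.get(c, 0)}<{min_n}; nearest tree neighbor")
            )

    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            mab, mba = float(mis.loc[a, b]), float(mis.loc[b, a])
            if mab >= mutual_cutoff and mba >= mutual_cutoff:
                uf.union(a, b)
                evidence_raw.append(
                    (a, b, "mutual-misassignment", f"m[{a},{b}]={mab:.2f}, m[{b},{a}]={mba:.2f}")
                )

    groups: dict[str, set] = {}
    for c in cols:
        groups.setdefault(uf.find(c), set()).add(c)
    unions = [frozenset(g) for g in groups.values() if len(g) > 1]
    unions.sort(key=lambda u: min(cols.index(c) for c in u))
    evidence: dict[frozenset, list[tuple[str, str]]] = {u: [] for u in unions}
    for a, b, rule, detail in evidence_raw:
        for u in unions:
            if a in u and b in u:
                evidence[u].append((rule, f"{a}+{b}: {detail}"))
                break
    return MergeProposal(unions=unions, evidence=evidence)


def apply_ru_map(
    baseline: BaselineCollection, unions: list[frozenset | set]
) -> BaselineCollection:
    """Rewrite the collection -> reporting-unit map from proposed unions.

    Each union becomes one reporting unit named by joining its member
    codes with ``/`` (in collection order); untouched collections report
    as themselves.  Genotypes are never modified.  A collection named in
    two unions is an error.
    """
    seen: set[str] = set()
    for u in unions:
        for c in u:
            if c not in baseline.collections:
                raise ValueError(f"unknown collection in union: {c!r}")
            if c in seen:
                raise ValueError(f"collection {c!r} appears in more than one union")
            seen.add(c)
    ru_map: dict[str, str] = {}
    order = {c: k for k, c in enumerate(baseline.collections)}
    for c in baseline.collections:
        ru_map[c] = c
    for u in unions:
        name = "/".join(sorted(u, key=order.get))
        for c in u:
            ru_map[c] = name
    return baseline.with_ru_map(ru_map)
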