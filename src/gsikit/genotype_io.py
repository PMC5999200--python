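"""Genotype tables, allele indexing, and file I/O.

The canonical on-disk format is a "wide" CSV with two columns per locus
(``LocusA``, ``LocusA.1``), one row per individual, and optional
``collection`` / ``repunit`` columns carrying baseline labels.  A small
genepop reader/writer is included for interoperability with classical
population-genetics tooling.

Allele labels are opaque strings: fragment lengths ("120") and
sequence-derived names ("ACG7") are equally valid.  Heterozygote call
order is normalized on read so that (a, b) and (b, a) are the same call.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = None

#: cell values treated as a missing allele call in the wide CSV dialect
_MISSING_TOKENS = {"", "0", "NA", "na", "NaN", "nan", "-", "?"}


def _is_missing_token(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and np.isnan(v):
        return True
    return str(v).strip() in _MISSING_TOKENS


@dataclass
class GenotypeTable:
    """Diploid multilocus genotypes for a set of individuals.

    ``calls`` is an (N, L) object array; each entry is either ``None``
    (missing) or a sorted 2-tuple of allele-label strings.
    """

    individuals: list[str]
    loci: list[str]
    calls: np.ndarray
    labels: list[str] | None = None
    repunits: list[str] | None = None

    def __post_init__(self):
        if len(set(self.individuals)) != len(self.individuals):
            dupes = sorted({i for i in self.individuals if self.individuals.count(i) > 1})
            raise ValueError(f"duplicate individual ID(s): {', '.join(dupes)}")
        if self.calls.shape != (len(self.individuals), len(self.loci)):
            raise ValueError("calls array shape does not match individuals x loci")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def missing_fraction(self) -> np.ndarray:
        """Per-individual fraction of loci with a missing call."""
        if self.n_individuals == 0 or self.n_loci == 0:
            return np.zeros(self.n_individuals)
        miss = np.array(
            [[self.calls[i, l] is None for l in range(self.n_loci)] for i in range(self.n_individuals)],
            dtype=bool,
        )
        return miss.mean(axis=1)

    def subset_individuals(self, keep_idx) -> "GenotypeTable":
        keep_idx = list(keep_idx)
        return GenotypeTable(
            individuals=[self.individuals[i] for i in keep_idx],
            loci=list(self.loci),
            calls=self.calls[keep_idx, :].copy(),
            labels=[self.labels[i] for i in keep_idx] if self.labels is not None else None,
            repunits=[self.repunits[i] for i in keep_idx] if self.repunits is not None else None,
        )

    def subset_loci(self, loci: list[str]) -> "GenotypeTable":
        idx = [self.loci.index(l) for l in loci]
        return GenotypeTable(
            individuals=list(self.individuals),
            loci=list(loci),
            calls=self.calls[:, idx].copy(),
            labels=list(self.labels) if self.labels is not None else None,
            repunits=list(self.repunits) if self.repunits is not None else None,
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.loci == other.loci
            and self.labels == other.labels
            and all(
                self.calls[i, l] == other.calls[i, l]
                for i in range(self.n_individuals)
                for l in range(self.n_loci)
            )
        )


@dataclass
class AlleleIndex:
    """Per-locus bijection between allele labels and dense integers.

    ``alleles[l]`` is the sorted list of distinct labels at locus ``l``;
    the integer code of a label is its position in that list.
    """

    loci: list[str]
    alleles: list[list[str]]

    @property
    def n_alleles(self) -> np.ndarray:
        return np.array([len(a) for a in self.alleles], dtype=int)

    @property
    def total_alleles(self) -> int:
        return int(self.n_alleles.sum())

    @property
    def mean_alleles_per_locus(self) -> float:
        """Mean over loci with at least one observed allele, 1 decimal."""
        counts = self.n_alleles
        counts = counts[counts > 0]
        return round(float(counts.mean()), 1) if counts.size else 0.0

    @property
    def empty_loci(self) -> list[str]:
        return [loc for loc, a in zip(self.loci, self.alleles) if len(a) == 0]

    def code(self, locus_idx: int, label: str) -> int:
        return self.alleles[locus_idx].index(label)

    def encode(self, table: GenotypeTable) -> np.ndarray:
        """Integer-encode a table against this index.

        Returns an (N, L, 2) int array with -1 for missing gene copies.
        Raises ``KeyError`` if the table carries an allele absent from
        the index (build the index on baseline plus mixture first).
        """
        if table.loci != self.loci:
            raise ValueError("locus list mismatch between table and index")
        lut = [{lab: k for k, lab in enumerate(a)} for a in self.alleles]
        out = np.full((table.n_individuals, table.n_loci, 2), -1, dtype=np.int32)
        for i in range(table.n_individuals):
            for l in range(table.n_loci):
                call = table.calls[i, l]
                if call is None:
                    continue
                try:
                    out[i, l, 0] = lut[l][call[0]]
                    out[i, l, 1] = lut[l][call[1]]
                except KeyError as exc:
                    raise KeyError(
                        f"allele {exc.args[0]!r} at locus {self.loci[l]!r} absent from index"
                    ) from None
        return out

    def decode(self, locus_idx: int, code: int) -> str:
        return self.alleles[locus_idx][code]


@dataclass
class BaselineCollection:
    """Labeled baseline genotypes plus the collection -> reporting-unit map."""

    genotypes: GenotypeTable
    collections: list[str]
    ru_map: dict[str, str]

    def __post_init__(self):
        if self.genotypes.labels is None:
            raise ValueError("baseline genotypes must carry collection labels")
        known = set(self.collections)
        stray = sorted({c for c in self.genotypes.labels if c not in known})
        if stray:
            raise ValueError(f"individual label(s) not in collection list: {', '.join(stray)}")
        unmapped = sorted(known - set(self.ru_map))
        if unmapped:
            raise ValueError(f"collection(s) missing from ru_map: {', '.join(unmapped)}")

    @property
    def reporting_units(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.collections:
            seen.setdefault(self.ru_map[c], None)
        return list(seen)

    def collection_sizes(self) -> dict[str, int]:
        sizes = {c: 0 for c in self.collections}
        for lab in self.genotypes.labels:
            sizes[lab] += 1
        return sizes

    def with_ru_map(self, ru_map: dict[str, str]) -> "BaselineCollection":
        return BaselineCollection(self.genotypes, list(self.collections), dict(ru_map))


# ---------------------------------------------------------------------------
# wide CSV dialect
# ---------------------------------------------------------------------------

def _norm_call(a, b):
    a_miss, b_miss = _is_missing_token(a), _is_missing_token(b)
    if a_miss and b_miss:
        return None
    if a_miss or b_miss:
        # half-calls are treated as missing: a diploid call needs 2 copies
        return None
    a, b = str(a).strip(), str(b).strip()
    return (a, b) if a <= b else (b, a)


def read_genotypes(path, dialect: str = "wide_csv") -> GenotypeTable:
    """Read a genotype table (``wide_csv`` or ``genepop`` dialect)."""
    if dialect == "wide_csv":
        return _read_wide_csv(path)
    if dialect == "genepop":
        return read_genepop(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_wide_csv(path) -> GenotypeTable:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if not cols or cols[0] != "indiv":
        raise ValueError("wide CSV must start with an 'indiv' column")
    meta = ["indiv"]
    for c in ("collection", "repunit"):
        if c in cols:
            meta.append(c)
    locus_cols = [c for c in cols if c not in meta]
    if len(locus_cols) % 2 != 0:
        raise ValueError(f"odd number of allele columns ({len(locus_cols)}): two per locus required")
    loci = []
    for j in range(0, len(locus_cols), 2):
        a, b = locus_cols[j], locus_cols[j + 1]
        if b != a + ".1":
            raise ValueError(f"allele columns must come in pairs 'L','L.1'; got {a!r},{b!r}")
        loci.append(a)
    individuals = [str(v) for v in df["indiv"]]
    calls = np.empty((len(individuals), len(loci)), dtype=object)
    for l, loc in enumerate(loci):
        a_col, b_col = df[loc].tolist(), df[loc + ".1"].tolist()
        for i in range(len(individuals)):
            calls[i, l] = _norm_call(a_col[i], b_col[i])
    labels = [str(v) for v in df["collection"]] if "collection" in df.columns else None
    repunits = [str(v) for v in df["repunit"]] if "repunit" in df.columns else None
    return GenotypeTable(individuals, loci, calls, labels, repunits)


def write_genotypes(table: GenotypeTable, path, dialect: str = "wide_csv") -> None:
    if dialect == "wide_csv":
        _write_wide_csv(table, path)
    elif dialect == "genepop":
        write_genepop(table, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _write_wide_csv(table: GenotypeTable, path) -> None:
    data: dict[str, list] = {"indiv": table.individuals}
    if table.labels is not None:
        data["collection"] = table.labels
    if table.repunits is not None:
        data["repunit"] = table.repunits
    for l, loc in enumerate(table.loci):
        a_col, b_col = [], []
        for i in range(table.n_individuals):
            call = table.calls[i, l]
            a_col.append("" if call is None else call[0])
            b_col.append("" if call is None else call[1])
        data[loc] = a_col
        data[loc + ".1"] = b_col
    pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# genepop dialect (4-digit genotypes: 2 digits per allele; 6-digit accepted)
# ---------------------------------------------------------------------------

def read_genepop(path) -> GenotypeTable:
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise ValueError("empty genepop file")
    body = lines[1:]  # first line is a free-text title
    loci: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().lower() != "pop":
        # locus names: one per line, or comma-separated on one line
        loci.extend([t.strip() for t in body[i].split(",") if t.strip()])
        i += 1
    if i == len(body):
        raise ValueError("genepop file has no 'pop' line")
    individuals, labels, rows = [], [], []
    pop_idx = 0
    while i < len(body):
        if body[i].strip().lower() == "pop":
            pop_idx += 1
            i += 1
            continue
        line = body[i].strip()
        i += 1
        if not line:
            continue
        if "," not in line:
            raise ValueError(f"malformed genepop individual line: {line!r}")
        name, geno = line.split(",", 1)
        tokens = geno.split()
        if len(tokens) != len(loci):
            raise ValueError(
                f"individual {name.strip()!r} has {len(tokens)} genotypes, expected {len(loci)}"
            )
        row = []
        for tok in tokens:
            if len(tok) not in (4, 6) or not tok.isdigit():
                raise ValueError(f"bad genepop genotype token {tok!r}")
            half = len(tok) // 2
            a, b = int(tok[:half]), int(tok[half:])
            row.append(None if a == 0 or b == 0 else _norm_call(str(a), str(b)))
        individuals.append(name.strip())
        labels.append(f"pop{pop_idx}")
        rows.append(row)
    calls = np.empty((len(individuals), len(loci)), dtype=object)
    for r, row in enumerate(rows):
        for c, v in enumerate(row):
            calls[r, c] = v
    return GenotypeTable(individuals, loci, calls, labels or None)


def write_genepop(table: GenotypeTable, path, title: str = "gsikit export") -> None:
    """Write a genepop file; allele labels must be integers below 1000."""
    width = 2
    for l in range(table.n_loci):
        for i in range(table.n_individuals):
            call = table.calls[i, l]
            if call is None:
                continue
            for lab in call:
                v = int(lab)  # raises for non-numeric labels
                if v >= 100:
                    width = 3
                if v >= 1000 or v < 1:
                    raise ValueError(f"allele label {lab!r} out of genepop code range 1-999")
    labels = table.labels or ["pop1"] * table.n_individuals
    order: dict[str, None] = {}
    for lab in labels:
        order.setdefault(lab, None)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(title + "\n")
        for loc in table.loci:
            fh.write(loc + "\n")
        for pop in order:
            fh.write("pop\n")
            for i, ind in enumerate(table.individuals):
                if labels[i] != pop:
                    continue
                toks = []
                for l in range(table.n_loci):
                    call = table.calls[i, l]
                    if call is None:
                        toks.append("0" * (2 * width))
                    else:
                        toks.append(f"{int(call[0]):0{width}d}{int(call[1]):0{width}d}")
                fh.write(f"{ind} , " + " ".join(toks) + "\n")


# ---------------------------------------------------------------------------
# filtering and indexing
# ---------------------------------------------------------------------------

def filter_missing_individuals(
    table: GenotypeTable, max_missing_frac: float = 0.5
) -> tuple[GenotypeTable, list[str]]:
    """Drop individuals with strictly more than ``max_missing_frac`` missing loci.

    Returns the filtered table and the list of removed individual IDs.
    The boundary is strict: an individual missing exactly the threshold
    fraction is retained.
    """
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ValueError("max_missing_frac must be in [0, 1]")
    frac = table.missing_fraction()
    keep = [i for i in range(table.n_individuals) if frac[i] <= max_missing_frac]
    removed = [table.individuals[i] for i in range(table.n_individuals) if frac[i] > max_missing_frac]
    return table.subset_individuals(keep), removed


def build_allele_index(table: GenotypeTable, extra: GenotypeTable | None = None) -> AlleleIndex:
    """Collect sorted distinct allele labels per locus.

    ``extra`` lets callers union a mixture table into the baseline index so
    alleles private to the mixture are representable.  Loci with zero
    non-missing calls get an empty allele list (``A_l = 0``) and appear in
    ``AlleleIndex.empty_loci``.
    """
    if table.n_individuals == 0 and extra is None:
        raise ValueError("cannot index an empty table")
    tables = [table] + ([extra] if extra is not None else [])
    for t in tables[1:]:
        if t.loci != table.loci:
            raise ValueError("locus list mismatch")
    alleles: list[list[str]] = []
    for l in range(table.n_loci):
        seen: set[str] = set()
        for t in tables:
            for i in range(t.n_individuals):
                call = t.calls[i, l]
                if call is not None:
                    seen.update(call)
        alleles.append(sorted(seen))
    return AlleleIndex(list(table.loci), alleles)


def read_baseline(path, ru_map_path=None, max_missing_frac: float = 0.5) -> BaselineCollection:
    """Read a labeled wide CSV (plus optional 2-column ru_map CSV) as a baseline.

    Applies the missing-data individual filter before assembly.  If no
    ru_map is given and the CSV lacks a ``repunit`` column, each collection
    reports as itself.
    """
    table = read_genotypes(path, "wide_csv")
    if table.labels is None:
        raise ValueError("baseline CSV must have a 'collection' column")
    table, _removed = filter_missing_individuals(table, max_missing_frac)
    collections: dict[str, None] = {}
    for lab in table.labels:
        collections.setdefault(lab, None)
    collections = list(collections)
    if ru_map_path is not None:
        m = pd.read_csv(ru_map_path, dtype=str)
        ru_map = dict(zip(m.iloc[:, 0], m.iloc[:, 1]))
    elif table.repunits is not None:
        ru_map = {c: r for c, r in zip(table.labels, table.repunits)}
    else:
        ru_map = {c: c for c in collections}
    return BaselineCollection(table, collections, ru_map)


def table_from_records(
    records: dict[str, list], loci: list[str], labels: list[str] | None = None
) -> GenotypeTable:
    """Build a table from {indiv: [(a,b)|None per locus]} — handy in tests."""
    individuals = list(records)
    calls = np.empty((len(individuals), len(loci)), dtype=object)
    for i, ind in enumerate(individuals):
        for l, call in enumerate(records[ind]):
            calls[i, l] = None if call is None else _norm_call(call[0], call[1])
    return GenotypeTable(individuals, loci, calls, labels)
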