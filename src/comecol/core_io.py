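"""Core data structures and file I/O.

Houses the validated OTU count table, sample metadata, rooted phylogeny and
distance-matrix containers, plus the standard-format readers/writers and the
two preprocessing steps every downstream analysis assumes: rare-taxon
filtering and rarefaction.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OtuTable",
    "SampleMetadata",
    "PhyloTree",
    "DistanceMatrix",
    "ValidationError",
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "write_metadata",
    "read_tree",
    "filter_otus",
    "rarefy",
    "aggregate_by_rank",
]


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {kind} identifier: {x!r}")
        seen.add(x)


@dataclass
class OtuTable:
    """Taxa x samples non-negative integer count matrix.

    All-zero taxon rows are dropped at construction with a logged warning;
    counts are stored as integers and relative abundances are always derived
    views, never stored.
    """

    counts: np.ndarray
    taxon_ids: list[str]
    sample_ids: list[str]
    taxonomy: dict[str, str] | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix (taxa x samples)")
        if counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.allclose(counts, rounded, atol=1e-9):
                raise ValidationError("counts must be integers")
            counts = rounded.astype(np.int64)
        else:
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            t, s = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"negative count at taxon {self.taxon_ids[t]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        _check_unique(self.taxon_ids, "taxon")
        _check_unique(self.sample_ids, "sample")
        keep = counts.sum(axis=1) > 0
        if not keep.all():
            dropped = [t for t, k in zip(self.taxon_ids, keep) if not k]
            logger.warning("dropping %d all-zero taxon rows: %s", len(dropped), dropped)
            warnings.warn(
                f"dropped {len(dropped)} all-zero taxon rows", stacklevel=2
            )
            counts = counts[keep]
            self.taxon_ids = [t for t, k in zip(self.taxon_ids, keep) if k]
        self.counts = counts
        self.taxon_ids = list(self.taxon_ids)
        self.sample_ids = list(self.sample_ids)

    # -- derived views ----------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def taxon_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> np.ndarray:
        """Per-sample relative abundances (columns sum to 1)."""
        totals = self.sample_totals().astype(float)
        if (totals == 0).any():
            raise ValidationError("sample with zero total count")
        return self.counts / totals

    def presence(self) -> np.ndarray:
        return self.counts > 0

    def subset_samples(self, sample_ids: Sequence[str], drop_empty_taxa: bool = True) -> "OtuTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        counts = self.counts[:, idx]
        if drop_empty_taxa:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return OtuTable(counts, list(self.taxon_ids), list(sample_ids), self.taxonomy)
        return OtuTable(counts, list(self.taxon_ids), list(sample_ids), self.taxonomy)

    def subset_taxa(self, taxon_ids: Sequence[str]) -> "OtuTable":
        idx = [self.taxon_ids.index(t) for t in taxon_ids]
        return OtuTable(self.counts[idx], list(taxon_ids), list(self.sample_ids), self.taxonomy)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)


@dataclass
class SampleMetadata:
    """Per-sample annotations keyed by sample_id.

    Carries at minimum a ``sample_id`` column; grouping columns (site, niche,
    block, env group ...) are free-form.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if "sample_id" not in self.frame.columns:
            raise ValidationError("metadata must contain a 'sample_id' column")
        ids = self.frame["sample_id"].astype(str).tolist()
        _check_unique(ids, "sample")
        self.frame = self.frame.copy()
        self.frame["sample_id"] = ids

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    def validate_against(self, table: OtuTable) -> None:
        """Every analyzed sample must have exactly one metadata row."""
        missing = set(table.sample_ids) - set(self.sample_ids)
        if missing:
            raise ValidationError(f"samples missing from metadata: {sorted(missing)}")

    def groups(self, table: OtuTable, column: str) -> np.ndarray:
        """Group labels for `column`, aligned to the table's sample order."""
        if column not in self.frame.columns:
            raise ValidationError(f"metadata has no column {column!r}")
        self.validate_against(table)
        lookup = dict(zip(self.sample_ids, self.frame[column]))
        return np.asarray([lookup[s] for s in table.sample_ids])


class PhyloTree:
    """Rooted tree over taxon ids with non-negative branch lengths."""

    def __init__(self, tree: dendropy.Tree, default_zero_lengths: bool = False):
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        _check_unique(labels, "tip")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                if default_zero_lengths:
                    edge.length = 0.0
                else:
                    raise ValidationError("tree edge missing a branch length")
            if edge.length < 0:
                raise ValidationError("negative branch length")
        self._labels = labels

    @property
    def tip_labels(self) -> list[str]:
        return list(self._labels)

    @property
    def n_tips(self) -> int:
        return len(self._labels)

    @classmethod
    def from_newick(cls, newick: str, default_zero_lengths: bool = False) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises assorted error types
            raise ValidationError(f"unreadable newick: {exc}") from exc
        return cls(tree, default_zero_lengths=default_zero_lengths)

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    def prune(self, taxa: Iterable[str]) -> "PhyloTree":
        """Restrict to a taxon subset; cophenetic distances among retained
        tips are preserved."""
        wanted = set(taxa)
        missing = wanted - set(self._labels)
        if missing:
            raise ValidationError(f"taxa not in tree: {sorted(missing)}")
        clone = self._tree.clone(depth=1)
        clone.retain_taxa_with_labels(sorted(wanted))
        return PhyloTree(clone)

    def cophenetic(self, taxa: Sequence[str] | None = None) -> "DistanceMatrix":
        """Patristic (branch-length path) distances between tips."""
        if taxa is None:
            taxa = self._labels
        else:
            missing = set(taxa) - set(self._labels)
            if missing:
                raise ValidationError(f"taxa not in tree: {sorted(missing)}")
        pdm = self._tree.phylogenetic_distance_matrix()
        tax_by_label = {t.label: t for t in self._tree.taxon_namespace}
        n = len(taxa)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = pdm.patristic_distance(
                    tax_by_label[taxa[i]], tax_by_label[taxa[j]]
                )
        return DistanceMatrix(d, list(taxa))

    def tip_depths(self) -> dict[str, float]:
        depths = {}
        for leaf in self._tree.leaf_node_iter():
            depths[leaf.taxon.label] = leaf.distance_from_root()
        return depths


@dataclass
class DistanceMatrix:
    """Square symmetric non-negative matrix with zero diagonal over ids."""

    data: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if data.shape != (n, n):
            raise ValidationError(f"distance matrix shape {data.shape} != ({n},{n})")
        finite = np.isfinite(data)
        if not np.all(np.abs(np.where(finite & finite.T, data - data.T, 0.0)) <= 1e-10):
            raise ValidationError("distance matrix not symmetric within 1e-10")
        if not np.all(np.diag(data) == 0):
            raise ValidationError("distance matrix diagonal must be exactly zero")
        if np.any(data[finite] < 0):
            raise ValidationError("negative distances")
        _check_unique(self.ids, "id")
        self.data = data
        self.ids = list(self.ids)

    @classmethod
    def unchecked(cls, data: np.ndarray, ids: Sequence[str]) -> "DistanceMatrix":
        """Bypass validation for matrices of standardized scores (which may
        be negative or NaN) that still want the square-matrix plumbing."""
        obj = cls.__new__(cls)
        obj.data = np.asarray(data, dtype=float)
        obj.ids = list(ids)
        return obj

    @property
    def n(self) -> int:
        return len(self.ids)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.ids.index(pair[0]), self.ids.index(pair[1])
        return float(self.data[i, j])

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(self.data[np.ix_(idx, idx)], list(ids))

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.data[iu]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_biom_json(path: Path) -> OtuTable:
    """Minimal BIOM-JSON reader (dense or sparse 'matrix_element_type')."""
    doc = json.loads(path.read_text())
    rows = [r["id"] for r in doc["rows"]]
    cols = [c["id"] for c in doc["columns"]]
    counts = np.zeros((len(rows), len(cols)))
    if doc.get("matrix_type") == "dense":
        counts[:] = np.asarray(doc["data"])
    else:
        for i, j, v in doc["data"]:
            counts[int(i), int(j)] = v
    taxonomy = None
    if any(r.get("metadata") and "taxonomy" in (r["metadata"] or {}) for r in doc["rows"]):
        taxonomy = {}
        for r in doc["rows"]:
            md = r.get("metadata") or {}
            tax = md.get("taxonomy")
            if tax is not None:
                taxonomy[r["id"]] = ";".join(tax) if isinstance(tax, list) else str(tax)
    return OtuTable(counts, rows, cols, taxonomy)


def read_otu_table(path: str | Path, orientation: str = "taxa_rows") -> OtuTable:
    """Read a TSV (or BIOM-style JSON) count table into an OtuTable.

    TSV layout: first column holds identifiers; an optional trailing
    ``taxonomy`` column carries semicolon-delimited lineage strings.
    ``orientation`` declares whether rows are taxa or samples; the result is
    always taxa x samples.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".json", ".biom"}:
        table = _read_biom_json(path)
        if orientation == "samples_rows":
            table = OtuTable(table.counts.T, table.sample_ids, table.taxon_ids)
        return table
    if orientation not in {"taxa_rows", "samples_rows"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", header=0, dtype=str, comment=None)
    id_col = df.columns[0]
    ids = df[id_col].astype(str).tolist()
    taxonomy = None
    value_cols = [c for c in df.columns[1:]]
    if value_cols and value_cols[-1].lower() == "taxonomy":
        taxonomy = dict(zip(ids, df[value_cols[-1]].astype(str)))
        value_cols = value_cols[:-1]
    counts = np.zeros((len(ids), len(value_cols)), dtype=np.int64)
    for j, col in enumerate(value_cols):
        for i, raw in enumerate(df[col]):
            try:
                v = int(raw)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"cell at row {ids[i]!r}, column {col!r} is not an integer: {raw!r}"
                ) from None
            if v < 0:
                raise ValidationError(
                    f"negative count at row {ids[i]!r}, column {col!r}: {raw!r}"
                )
            counts[i, j] = v
    if orientation == "samples_rows":
        return OtuTable(counts.T, value_cols, ids, None)
    return OtuTable(counts, ids, value_cols, taxonomy)


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    df = table.to_dataframe()
    df.index.name = "#OTU_ID"
    if table.taxonomy:
        df = df.copy()
        df["taxonomy"] = [table.taxonomy.get(t, "") for t in table.taxon_ids]
    df.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.frame.to_csv(path, sep="\t", index=False)


def read_tree(path: str | Path, default_zero_lengths: bool = False) -> PhyloTree:
    """Read a newick tree with branch lengths."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return PhyloTree.from_newick(path.read_text(), default_zero_lengths=default_zero_lengths)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def filter_otus(
    table: OtuTable,
    min_rel_abund: float = 5e-5,
    drop_singletons: bool = True,
) -> OtuTable:
    """Drop singleton taxa and taxa below a whole-dataset abundance fraction.

    The relative-abundance denominator is the pre-filter grand total; both
    rules are evaluated on the input table, so the operation is idempotent.
    Returns a new table and logs counts removed per rule.
    """
    if not (0 <= min_rel_abund < 1):
        raise ValueError("min_rel_abund must be in [0, 1)")
    totals = table.taxon_totals()
    grand = totals.sum()
    keep = np.ones(table.n_taxa, dtype=bool)
    n_singletons = n_rare = 0
    if drop_singletons:
        singleton = totals == 1
        n_singletons = int(singleton.sum())
        keep &= ~singleton
    if min_rel_abund > 0:
        rare = (totals / grand) < min_rel_abund
        n_rare = int((rare & keep).sum())
        keep &= ~rare
    if not keep.any():
        raise ValidationError("all taxa filtered: nothing left after abundance filter")
    logger.info(
        "filter_otus removed %d singletons and %d taxa below %.4g%% relative abundance",
        n_singletons, n_rare, 100 * min_rel_abund,
    )
    return OtuTable(
        table.counts[keep],
        [t for t, k in zip(table.taxon_ids, keep) if k],
        list(table.sample_ids),
        table.taxonomy,
    )


def rarefy(
    table: OtuTable,
    depth: int,
    seed: int,
    drop_shallow: bool = False,
) -> OtuTable:
    """Subsample each sample to exactly `depth` reads without replacement."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    totals = table.sample_totals()
    if (totals < depth).all():
        raise ValueError(f"no sample reaches depth {depth} (max total {totals.max()})")
    shallow = totals < depth
    if shallow.any():
        if not drop_shallow:
            bad = [s for s, sh in zip(table.sample_ids, shallow) if sh]
            raise ValueError(
                f"samples shallower than depth {depth}: {bad}; set drop_shallow to drop them"
            )
        warnings.warn(
            f"dropping {int(shallow.sum())} samples shallower than {depth}", stacklevel=2
        )
    rng = np.random.default_rng(seed)
    keep_cols = ~shallow
    out = np.zeros((table.n_taxa, int(keep_cols.sum())), dtype=np.int64)
    j_out = 0
    for j in range(table.n_samples):
        if shallow[j]:
            continue
        col = table.counts[:, j]
        out[:, j_out] = rng.multivariate_hypergeometric(col, depth)
        j_out += 1
    sample_ids = [s for s, k in zip(table.sample_ids, keep_cols) if k]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rarefaction may zero out rare taxa
        return OtuTable(out, list(table.taxon_ids), sample_ids, table.taxonomy)


def aggregate_by_rank(table: OtuTable, rank: int, sep: str = ";") -> OtuTable:
    """Sum counts by the lineage prefix of length `rank` (1-based ranks)."""
    if not table.taxonomy:
        raise ValidationError("table carries no taxonomy")
    keys = []
    for t in table.taxon_ids:
        lineage = table.taxonomy.get(t, "")
        parts = [p.strip() for p in lineage.split(sep)]
        keys.append(sep.join(parts[:rank]) if parts != [""] else "unclassified")
    order = list(dict.fromkeys(keys))
    counts = np.zeros((len(order), table.n_samples), dtype=np.int64)
    for key, row in zip(keys, table.counts):
        counts[order.index(key)] += row
    return OtuTable(counts, order, list(table.sample_ids), None)
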