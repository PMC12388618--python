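"""Reading, validating and stratifying the pipeline's tabular inputs.

The central container is :class:`CommunityTable`, a samples x OTUs abundance
matrix. Phylogenies are consumed as Newick and immediately reduced to a
patristic (tip-to-tip path length) distance matrix, which is all the
downstream phylogenetic null models need. Samples are stratified into
salinity levels (soil electrical conductivity bins, mS/cm) for the
per-level network and assembly analyses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CommunityTable",
    "SampleMetadata",
    "SalinityBinning",
    "PhylogeneticDistances",
    "read_community_table",
    "write_community_table",
    "to_relative",
    "read_phylogeny",
    "patristic_distances",
    "read_metadata",
    "assign_salinity_levels",
    "DEFAULT_BIN_EDGES",
]

#: Five-level salinity stratification (mS/cm). The gradient spans ~0-11 mS/cm;
#: edges are left-closed/right-open, last interval closed.
DEFAULT_BIN_EDGES = (0.0, 1.0, 2.0, 4.0, 7.0, 11.0)


@dataclass(frozen=True)
class CommunityTable:
    """Samples x OTUs abundance matrix with identifiers.

    Parameters
    ----------
    sample_ids : list of str
        Row identifiers, unique.
    otu_ids : list of str
        Column identifiers, unique.
    counts : ndarray, shape (n_samples, n_otus)
        Non-negative abundances; integer counts or relative abundances.
    is_relative : bool
        If True every row sums to 1 (within 1e-9).
    """

    sample_ids: tuple
    otu_ids: tuple
    counts: np.ndarray
    is_relative: bool = False

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "otu_ids", tuple(str(o) for o in self.otu_ids))
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D samples x OTUs matrix")
        if counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise ValueError("duplicate OTU identifiers")
        if not np.all(np.isfinite(counts)):
            raise ValueError("non-finite abundance values")
        if np.any(counts < 0):
            raise ValueError("negative abundance values")
        if self.is_relative:
            rowsum = counts.sum(axis=1)
            if not np.allclose(rowsum, 1.0, atol=1e-9):
                bad = [self.sample_ids[i] for i in np.flatnonzero(~np.isclose(rowsum, 1.0, atol=1e-9))]
                raise ValueError(f"is_relative but row sums != 1 for samples {bad[:5]}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.sample_ids), columns=list(self.otu_ids))

    def subset_samples(self, sample_ids) -> "CommunityTable":
        """Row-subset preserving the requested sample order."""
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise KeyError(f"unknown samples: {missing}")
        rows = [idx[s] for s in sample_ids]
        return CommunityTable(tuple(sample_ids), self.otu_ids, self.counts[rows], self.is_relative)

    def subset_otus(self, otu_ids) -> "CommunityTable":
        """Column subset. Dropping OTUs breaks compositional closure, so the
        result is never flagged relative; renormalize downstream if needed."""
        idx = {o: i for i, o in enumerate(self.otu_ids)}
        missing = [o for o in otu_ids if o not in idx]
        if missing:
            raise KeyError(f"unknown OTUs: {missing}")
        cols = [idx[o] for o in otu_ids]
        return CommunityTable(self.sample_ids, tuple(otu_ids), self.counts[:, cols], False)


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample metadata: site and soil salinity (mS/cm), plus covariates."""

    sample_id: str
    site_id: str
    salinity: float
    covariates: dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.isfinite(self.salinity) or self.salinity < 0:
            raise ValueError(f"sample {self.sample_id}: salinity must be finite and >= 0")


@dataclass(frozen=True)
class SalinityBinning:
    """Left-closed/right-open salinity intervals; the last interval is closed."""

    bin_edges: tuple = DEFAULT_BIN_EDGES
    bin_labels: tuple = None

    def __post_init__(self):
        edges = tuple(float(e) for e in self.bin_edges)
        object.__setattr__(self, "bin_edges", edges)
        if len(edges) < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing with >= 2 edges")
        if self.bin_labels is None:
            labels = tuple(f"{lo:g}-{hi:g}" for lo, hi in zip(edges[:-1], edges[1:]))
            object.__setattr__(self, "bin_labels", labels)
        else:
            object.__setattr__(self, "bin_labels", tuple(self.bin_labels))
        if len(self.bin_labels) != len(edges) - 1:
            raise ValueError("need exactly one label per interval")

    def assign(self, salinity: float) -> str:
        edges = self.bin_edges
        if salinity < edges[0] or salinity > edges[-1]:
            raise ValueError(f"salinity {salinity} outside binning range [{edges[0]}, {edges[-1]}]")
        if salinity == edges[-1]:  # last interval right-closed
            return self.bin_labels[-1]
        i = int(np.searchsorted(edges, salinity, side="right")) - 1
        return self.bin_labels[i]


class PhylogeneticDistances:
    """Symmetric patristic distance matrix over a fixed OTU ordering."""

    def __init__(self, otu_ids, matrix):
        self.otu_ids = tuple(str(o) for o in otu_ids)
        m = np.asarray(matrix, dtype=float)
        if m.shape != (len(self.otu_ids),) * 2:
            raise ValueError("matrix shape does not match otu_ids")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(m < 0):
            raise ValueError("negative distances")
        self.matrix = m
        self._index = {o: i for i, o in enumerate(self.otu_ids)}

    def __getitem__(self, pair):
        a, b = pair
        return self.matrix[self._index[a], self._index[b]]

    def reorder(self, otu_ids) -> "PhylogeneticDistances":
        missing = [o for o in otu_ids if o not in self._index]
        if missing:
            raise KeyError(f"OTUs absent from distance matrix: {missing}")
        idx = np.array([self._index[o] for o in otu_ids])
        return PhylogeneticDistances(otu_ids, self.matrix[np.ix_(idx, idx)])


def read_community_table(path, orientation: str = "samples_as_rows") -> CommunityTable:
    """Read a tab-separated OTU table (header row + first ID column).

    Parameters
    ----------
    orientation : {"samples_as_rows", "otus_as_rows"}
        Layout of the file; never guessed.
    """
    if orientation not in ("samples_as_rows", "otus_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):  # pandas silently mangles duplicates
        raise ValueError(f"{path}: duplicate column identifiers in header")
    df = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype={0: str})
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty table")
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate row or column identifiers")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cell: {exc}") from exc
    if orientation == "otus_as_rows":
        df = df.T
        values = values.T
    if np.any(values < 0) or not np.all(np.isfinite(values)):
        raise ValueError(f"{path}: negative or non-finite abundance values")
    return CommunityTable(tuple(df.index.astype(str)), tuple(df.columns.astype(str)), values)


def write_community_table(table: CommunityTable, path) -> None:
    """Write a table as TSV, samples as rows; integer counts stay integer."""
    df = table.to_dataframe()
    if not table.is_relative and np.allclose(table.counts, np.round(table.counts)):
        df = df.astype(np.int64)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def to_relative(table: CommunityTable) -> CommunityTable:
    """Convert counts to within-sample relative abundances (idempotent)."""
    if table.is_relative:
        return table
    rowsum = table.counts.sum(axis=1)
    zero = np.flatnonzero(rowsum == 0)
    if zero.size:
        raise ValueError(f"all-zero sample rows: {[table.sample_ids[i] for i in zero]}")
    return CommunityTable(table.sample_ids, table.otu_ids, table.counts / rowsum[:, None], True)


def patristic_distances(tree: dendropy.Tree, otu_ids) -> PhylogeneticDistances:
    """Tip-to-tip path-length distances for the requested tips, in order."""
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError(f"negative branch length {edge.length}")
    taxa = {t.label: t for t in tree.taxon_namespace}
    missing = [o for o in otu_ids if o not in taxa]
    if missing:
        raise KeyError(f"tips absent from tree: {missing}")
    pdm = tree.phylogenetic_distance_matrix()
    n = len(otu_ids)
    m = np.zeros((n, n))
    tips = [taxa[o] for o in otu_ids]
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(tips[i], tips[j])
            m[i, j] = m[j, i] = d
    return PhylogeneticDistances(otu_ids, m)


def read_phylogeny(path, otu_ids) -> PhylogeneticDistances:
    """Parse a Newick tree and return patristic distances over ``otu_ids``."""
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    return patristic_distances(tree, otu_ids)


def read_metadata(path) -> list:
    """Read per-sample metadata TSV (sample_id, site_id, salinity, extras)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "site_id": str})
    for col in ("sample_id", "site_id", "salinity"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column {col!r}")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample_id rows")
    extra = [c for c in df.columns if c not in ("sample_id", "site_id", "salinity")]
    out = []
    for _, row in df.iterrows():
        cov = {c: float(row[c]) for c in extra if np.isfinite(row[c])}
        out.append(SampleMetadata(row["sample_id"], row["site_id"], float(row["salinity"]), cov))
    return out


def validate_metadata(table: CommunityTable, meta) -> dict:
    """Check one metadata row per table sample; return sample_id -> metadata."""
    by_id = {m.sample_id: m for m in meta}
    missing = [s for s in table.sample_ids if s not in by_id]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")
    return {s: by_id[s] for s in table.sample_ids}


def assign_salinity_levels(meta, binning: SalinityBinning = None) -> dict:
    """Map every sample to its salinity level label (total, unambiguous)."""
    binning = binning or SalinityBinning()
    out = {}
    for m in meta:
        try:
            out[m.sample_id] = binning.assign(m.salinity)
        except ValueError as exc:
            raise ValueError(f"sample {m.sample_id}: {exc}") from exc
    return out
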