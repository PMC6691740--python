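"""Domain types and TSV/Newick/GraphML readers and writers.

All tabular formats are tab-separated UTF-8 with a mandatory header row;
lines starting with ``#`` are ignored. The canonical in-memory orientation
of a count table is samples x taxa; files may store either orientation and
declare it at read time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
import skbio

NICHES = ("air", "water", "rock", "sediment")
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


class FormatError(ValueError):
    """A file does not conform to the expected layout."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


# ---------------------------------------------------------------------------
# CountTable


@dataclass
class CountTable:
    """Non-negative integer abundance matrix, samples x taxa.

    Parameters
    ----------
    sample_ids : list of str
        Unique row labels.
    taxon_ids : list of str
        Unique column labels.
    counts : ndarray of shape (n_samples, n_taxa)
        Non-negative integers; every row sum must be positive.
    provenance : str
        Free-text tag describing the table's origin.
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    counts: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        _check_unique(self.sample_ids, "sample id")
        _check_unique(self.taxon_ids, "taxon id")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.mod(self.counts, 1) == 0):
                bad = np.argwhere(np.mod(self.counts, 1) != 0)[0]
                raise FormatError(
                    f"non-integer count at sample {self.sample_ids[bad[0]]!r}, "
                    f"taxon {self.taxon_ids[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            bad = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.sample_ids[bad[0]]!r}, "
                f"taxon {self.taxon_ids[bad[1]]!r}"
            )
        empties = [s for s, tot in zip(self.sample_ids, self.counts.sum(axis=1)) if tot == 0]
        if empties:
            raise ValidationError(f"samples with zero total counts: {empties}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)

    def select_taxa(self, taxon_ids: Iterable[str]) -> "CountTable":
        keep = list(taxon_ids)
        idx = [self.taxon_ids.index(t) for t in keep]
        return CountTable(list(self.sample_ids), keep, self.counts[:, idx], self.provenance)

    def select_samples(self, sample_ids: Iterable[str]) -> "CountTable":
        keep = list(sample_ids)
        idx = [self.sample_ids.index(s) for s in keep]
        return CountTable(keep, list(self.taxon_ids), self.counts[idx, :], self.provenance)


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what}: {i!r}")
        seen.add(i)


def read_count_table(path: str | Path, orientation: str = "taxa_rows") -> CountTable:
    """Read a TSV count table.

    ``orientation`` declares the file layout: ``"taxa_rows"`` (first column
    taxon ids, remaining columns one per sample — the common OTU-table
    export) or ``"samples_rows"``. The returned table is always samples x
    taxa.
    """
    if orientation not in ("taxa_rows", "samples_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    if df.empty:
        raise FormatError(f"{path}: no data rows")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell ({exc})") from exc
    if orientation == "taxa_rows":
        sample_ids = [str(c) for c in df.columns]
        taxon_ids = [str(i) for i in df.index]
        values = values.T
    else:
        sample_ids = [str(i) for i in df.index]
        taxon_ids = [str(c) for c in df.columns]
    return CountTable(sample_ids, taxon_ids, values, provenance=str(path))


def write_count_table(table: CountTable, path: str | Path, orientation: str = "taxa_rows") -> None:
    df = table.to_frame()
    if orientation == "taxa_rows":
        df = df.T
        df.index.name = "taxon_id"
    else:
        df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# TaxonomyMap


@dataclass
class TaxonomyMap:
    """taxon_id -> lineage tuple of up to 7 ranks; missing ranks are ''."""

    lineages: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for taxon, lin in self.lineages.items():
            lin = tuple(lin) + ("",) * (len(RANKS) - len(lin))
            if len(lin) > len(RANKS):
                raise ValidationError(f"taxon {taxon!r}: more than {len(RANKS)} ranks")
            self.lineages[taxon] = lin

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.lineages

    def rank(self, taxon: str, rank_name: str) -> str:
        return self.lineages[taxon][RANKS.index(rank_name)]

    def genus_label(self, taxon: str) -> str:
        """Genus label, falling back to ``<lowest assigned rank>__unclassified``."""
        lin = self.lineages[taxon]
        genus = lin[RANKS.index("genus")]
        if genus:
            return genus
        for name in reversed(lin[: RANKS.index("genus")]):
            if name:
                return f"{name}__unclassified"
        return "unclassified"


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str).fillna("")
    lineages = {str(t): tuple(str(v) for v in row) for t, row in zip(df.index, df.to_numpy())}
    return TaxonomyMap(lineages)


def write_taxonomy(tax: TaxonomyMap, path: str | Path) -> None:
    df = pd.DataFrame.from_dict(tax.lineages, orient="index", columns=list(RANKS))
    df.index.name = "taxon_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# SampleMetadata


@dataclass
class SampleMetadata:
    """Per-sample factors: cave, niche and environmental measurements.

    Backed by a DataFrame indexed by sample id. Missing values are NaN
    (encoded "NA" on disk); accessors drop samples with NA per variable.
    """

    frame: pd.DataFrame

    REQUIRED = ("cave_id", "niche")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.frame.columns:
                raise ValidationError(f"metadata missing required column {col!r}")
        bad = set(self.frame["niche"]) - set(NICHES)
        if bad:
            raise ValidationError(f"unknown niche levels: {sorted(bad)}; expected {NICHES}")
        _check_unique([str(i) for i in self.frame.index], "sample id")

    @property
    def sample_ids(self) -> list[str]:
        return [str(i) for i in self.frame.index]

    def niches(self, sample_ids: Iterable[str]) -> np.ndarray:
        return self.frame.loc[list(sample_ids), "niche"].to_numpy()

    def caves(self, sample_ids: Iterable[str]) -> np.ndarray:
        return self.frame.loc[list(sample_ids), "cave_id"].to_numpy()

    def variable(self, name: str, sample_ids: Iterable[str]) -> tuple[list[str], np.ndarray]:
        """Values of a numeric variable, dropping samples where it is NA."""
        sub = self.frame.loc[list(sample_ids), name]
        sub = sub[sub.notna()]
        return [str(i) for i in sub.index], sub.to_numpy(dtype=float)

    def check_covers(self, table: CountTable) -> None:
        missing = [s for s in table.sample_ids if s not in self.frame.index]
        if missing:
            raise ValidationError(f"samples absent from metadata: {missing}")


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, na_values=["NA"])
    df.index = df.index.astype(str)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    df = meta.frame.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# PhyloTree


@dataclass
class PhyloTree:
    """Rooted tree with uniquely-labelled leaves and non-negative branch lengths."""

    root: skbio.TreeNode

    def __post_init__(self) -> None:
        names = self.leaf_names()
        _check_unique(names, "leaf label")
        for node in self.root.traverse(include_self=False):
            if node.length is not None and (not np.isfinite(node.length) or node.length < 0):
                raise ValidationError(
                    f"branch above {node.name or '<internal>'!r} has invalid length {node.length}"
                )

    def leaf_names(self) -> list[str]:
        return [t.name for t in self.root.tips()]

    def patristic_distances(self) -> pd.DataFrame:
        dm = self.root.tip_tip_distances()
        return pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))

    def write(self, path: str | Path) -> None:
        self.root.write(str(path))


def read_newick(path: str | Path, expected_taxa: Iterable[str] | None = None) -> PhyloTree:
    try:
        root = skbio.TreeNode.read(str(path))
    except Exception as exc:  # skbio raises its own parse error hierarchy
        raise FormatError(f"{path}: cannot parse Newick ({exc})") from exc
    tree = PhyloTree(root)
    if expected_taxa is not None:
        missing = sorted(set(expected_taxa) - set(tree.leaf_names()))
        if missing:
            warnings.warn(f"tree is missing {len(missing)} taxa: {missing[:10]}", stacklevel=2)
    return tree


# ---------------------------------------------------------------------------
# Network serialization


def write_network(net: nx.Graph, path_prefix: str | Path) -> tuple[Path, Path]:
    """Write a co-occurrence network as GraphML plus an edge-list CSV.

    Returns the (graphml_path, csv_path) pair. Node attributes (genus,
    phylum, module, betweenness, ...) and the edge attributes rho/p/q are
    carried into the GraphML; the CSV has columns source,target,rho,p,q.
    """
    prefix = Path(path_prefix)
    graphml = prefix.with_suffix(".graphml")
    csv = prefix.with_suffix(".edges.csv")
    nx.write_graphml(net, graphml)
    rows = [
        {
            "source": u,
            "target": v,
            "rho": data.get("rho", np.nan),
            "p": data.get("p", np.nan),
            "q": data.get("q", np.nan),
        }
        for u, v, data in net.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "rho", "p", "q"]).to_csv(csv, index=False)
    return graphml, csv


def read_network(graphml_path: str | Path) -> nx.Graph:
    return nx.read_graphml(graphml_path)


# ---------------------------------------------------------------------------
# Misc table writers used by the CLI


def write_frame(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)
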