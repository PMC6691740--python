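"""Alpha diversity, beta dissimilarities, Sorensen partitioning and Venn counts."""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from otukit.normalize import AbundanceTable
from otukit.tables_io import CountTable, PhyloTree, ValidationError


@dataclass
class DistanceMatrix:
    """Symmetric pairwise sample dissimilarities with zero diagonal."""

    sample_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.sample_ids)
        if self.matrix.shape != (n, n):
            raise ValidationError("distance matrix shape does not match sample ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.abs(np.diag(self.matrix)) > 1e-12):
            raise ValidationError("distance matrix diagonal is not zero")
        if np.any(self.matrix < -1e-12):
            raise ValidationError("distance matrix has negative entries")
        np.fill_diagonal(self.matrix, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.sample_ids, columns=self.sample_ids)

    def submatrix(self, sample_ids: list[str]) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DistanceMatrix(list(sample_ids), self.matrix[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# Alpha diversity


def shannon(counts: np.ndarray) -> float:
    """Shannon entropy H = -sum p ln p over nonzero proportions (natural log)."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValidationError("cannot compute Shannon index of an all-zero row")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def chao1(counts: np.ndarray, bias_corrected: bool = False) -> float:
    """Chao1 richness from singleton (F1) and doubleton (F2) frequencies.

    Classic form: S_obs + F1^2 / (2 F2), falling back to
    S_obs + F1 (F1 - 1) / 2 when F2 = 0. Bias-corrected:
    S_obs + F1 (F1 - 1) / (2 (F2 + 1)).
    """
    counts = np.asarray(counts)
    if counts.sum() <= 0:
        raise ValidationError("cannot compute Chao1 of an all-zero row")
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def goods_coverage(counts: np.ndarray) -> float:
    """Good's coverage 1 - F1/N."""
    counts = np.asarray(counts)
    n = counts.sum()
    if n <= 0:
        raise ValidationError("cannot compute coverage of an all-zero row")
    f1 = int((counts == 1).sum())
    return 1.0 - f1 / n


def alpha_table(table: CountTable | AbundanceTable, bias_corrected: bool = False) -> pd.DataFrame:
    """Per-sample observed OTUs, Chao1, Shannon and Good's coverage."""
    values = table.values if isinstance(table, AbundanceTable) else table.counts
    records = []
    for sid, row in zip(table.sample_ids, values):
        records.append(
            {
                "sample_id": sid,
                "observed_otus": int((row > 0).sum()),
                "chao1": chao1(row, bias_corrected=bias_corrected),
                "shannon": shannon(row),
                "goods_coverage": goods_coverage(row),
            }
        )
    return pd.DataFrame(records).set_index("sample_id")


# ---------------------------------------------------------------------------
# Beta diversity


def bray_curtis(table: AbundanceTable | CountTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(x,y) = 1 - 2 sum min(x,y) / (sum x + sum y)."""
    values = table.values if isinstance(table, AbundanceTable) else table.counts.astype(float)
    sums = values.sum(axis=1)
    for i, j in itertools.combinations(range(len(sums)), 2):
        if sums[i] == 0 and sums[j] == 0:
            raise ValidationError(
                f"Bray-Curtis undefined for the all-zero pair "
                f"({table.sample_ids[i]}, {table.sample_ids[j]})"
            )
    d = squareform(pdist(values, metric="braycurtis"))
    return DistanceMatrix(list(table.sample_ids), d)


def weighted_unifrac(
    table: AbundanceTable | CountTable, tree: PhyloTree, normalized: bool = True
) -> DistanceMatrix:
    """Weighted UniFrac between all sample pairs.

    Raw form: sum over branches b of l_b * |A_b - B_b| where A_b is the
    fraction of sample A's total abundance descending from b. The
    normalized form divides by sum l_b * (A_b + B_b).
    """
    values = table.values if isinstance(table, AbundanceTable) else table.counts.astype(float)
    leaf_names = tree.leaf_names()
    missing = sorted(set(table.taxon_ids) - set(leaf_names))
    if missing:
        raise ValidationError(f"taxa missing from tree: {missing[:10]}")
    rel = values / values.sum(axis=1, keepdims=True)
    taxon_col = {t: i for i, t in enumerate(table.taxon_ids)}

    # per-branch descendant-abundance fractions, via postorder accumulation
    lengths: list[float] = []
    props: list[np.ndarray] = []
    partial: dict[int, np.ndarray] = {}
    n = values.shape[0]
    for node in tree.root.postorder(include_self=True):
        if node.is_tip():
            col = taxon_col.get(node.name)
            acc = rel[:, col].copy() if col is not None else np.zeros(n)
        else:
            acc = np.zeros(n)
            for child in node.children:
                acc += partial.pop(id(child))
        partial[id(node)] = acc
        if node is not tree.root and node.length is not None:
            lengths.append(float(node.length))
            props.append(acc)
    length_arr = np.array(lengths)
    prop_arr = np.array(props)  # branches x samples

    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(prop_arr[:, i][:, None] - prop_arr[:, i + 1:])
        num = (length_arr[:, None] * diff).sum(axis=0)
        if normalized:
            denom = (length_arr[:, None] * (prop_arr[:, i][:, None] + prop_arr[:, i + 1:])).sum(axis=0)
            with np.errstate(invalid="ignore"):
                num = np.where(denom > 0, num / denom, 0.0)
        d[i, i + 1:] = num
        d[i + 1:, i] = num
    return DistanceMatrix(list(table.sample_ids), d)


# ---------------------------------------------------------------------------
# Sorensen partitioning (turnover vs nestedness)


@dataclass
class BetaPartition:
    beta_sor: float
    beta_sim: float
    beta_sne: float


def beta_partition_pair(x: np.ndarray, y: np.ndarray) -> BetaPartition:
    """Partition pairwise Sorensen dissimilarity into turnover + nestedness.

    With a = shared species, b/c = uniques to each side:
    beta_sor = (b+c)/(2a+b+c); beta_sim = min(b,c)/(a+min(b,c));
    beta_sne = beta_sor - beta_sim.
    """
    x = np.asarray(x) > 0
    y = np.asarray(y) > 0
    if not x.any() or not y.any():
        raise ValidationError("beta partition needs at least one presence per community")
    a = int((x & y).sum())
    b = int((x & ~y).sum())
    c = int((~x & y).sum())
    if a + b + c == 0:
        raise ValidationError("no species present")
    beta_sor = (b + c) / (2 * a + b + c)
    m = min(b, c)
    beta_sim = m / (a + m) if (a + m) > 0 else 0.0
    return BetaPartition(beta_sor, beta_sim, beta_sor - beta_sim)


def beta_partition_table(table: CountTable | AbundanceTable) -> pd.DataFrame:
    """All pairwise Sorensen partitions of a table."""
    values = table.values if isinstance(table, AbundanceTable) else table.counts
    rows = []
    for i, j in itertools.combinations(range(len(table.sample_ids)), 2):
        part = beta_partition_pair(values[i], values[j])
        rows.append(
            {
                "sample_a": table.sample_ids[i],
                "sample_b": table.sample_ids[j],
                "beta_sor": part.beta_sor,
                "beta_sim": part.beta_sim,
                "beta_sne": part.beta_sne,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Shared / exclusive OTU counts


def venn_counts(table: CountTable, groups: Mapping[str, str] | Iterable[str]) -> dict[frozenset, int]:
    """OTU counts for every nonempty group subset.

    An OTU belongs to a group iff it has count > 0 in at least one of that
    group's samples; it is tallied under the exact set of groups where it
    occurs, so the counts partition the detected OTUs.
    """
    if isinstance(groups, Mapping):
        labels = np.array([groups[s] for s in table.sample_ids])
    else:
        labels = np.asarray(list(groups))
    levels = sorted(set(labels))
    if len(levels) < 2:
        raise ValidationError("venn_counts needs at least 2 groups")
    presence = {
        g: (table.counts[labels == g, :] > 0).any(axis=0) for g in levels
    }
    counts: dict[frozenset, int] = {}
    for r in range(1, len(levels) + 1):
        for combo in itertools.combinations(levels, r):
            key = frozenset(combo)
            inside = np.logical_and.reduce([presence[g] for g in combo])
            outside = np.logical_or.reduce(
                [presence[g] for g in levels if g not in key] or [np.zeros(table.n_taxa, bool)]
            )
            counts[key] = int((inside & ~outside).sum())
    return counts
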