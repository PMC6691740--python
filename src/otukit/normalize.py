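"""Table-level filters, normalizations and genus aggregation."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from otukit.tables_io import CountTable, TaxonomyMap, ValidationError

logger = logging.getLogger(__name__)


class ParameterError(ValueError):
    pass


class NormalizationError(ValueError):
    pass


@dataclass
class AbundanceTable:
    """Real-valued sample x taxon table tagged with its normalization method.

    method is one of {"relative", "cpm", "css", "rarefied"}. Relative rows
    sum to 1; rarefied rows sum to the target depth exactly.
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    values: np.ndarray
    method: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValidationError("abundance table has negative entries")
        if self.method not in ("relative", "cpm", "css", "rarefied"):
            raise ValidationError(f"unknown method tag {self.method!r}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.taxon_ids)

    def row(self, sample_id: str) -> np.ndarray:
        return self.values[self.sample_ids.index(sample_id)]


def filter_rare_otus(table: CountTable, threshold: float = 1e-5) -> CountTable:
    """Drop OTUs whose table-wide relative abundance is below ``threshold``.

    An OTU is retained iff total count of the OTU / total count of the
    table >= threshold.
    """
    if not 0 < threshold < 1:
        raise ParameterError(f"threshold must lie in (0, 1), got {threshold}")
    totals = table.counts.sum(axis=0)
    grand = table.counts.sum()
    keep = totals / grand >= threshold
    kept = [t for t, k in zip(table.taxon_ids, keep) if k]
    return CountTable(
        list(table.sample_ids), kept, table.counts[:, keep], table.provenance
    )


def rarefy(table: CountTable, depth: int | None = None, seed: int = 0) -> AbundanceTable:
    """Subsample each sample to ``depth`` reads without replacement.

    Each sample is drawn from the multivariate hypergeometric distribution,
    so the rarefied row sums to ``depth`` exactly and no taxon exceeds its
    original count. Samples with fewer than ``depth`` reads are dropped
    with a warning. ``depth=None`` uses the minimum sample total.

    Draws are made in a canonical taxon order (sorted by taxon id) so the
    result is invariant to column permutations under the same seed.
    """
    totals = table.counts.sum(axis=1)
    if depth is None:
        depth = int(totals.min())
    if depth < 1:
        raise ParameterError("rarefaction depth must be >= 1")
    order = np.argsort(np.array(table.taxon_ids))
    inverse = np.argsort(order)
    rng = np.random.default_rng(seed)
    rows, kept_samples = [], []
    for i, sid in enumerate(table.sample_ids):
        if totals[i] < depth:
            logger.warning("dropping sample %s: total %d < depth %d", sid, totals[i], depth)
            continue
        draw = rng.multivariate_hypergeometric(table.counts[i, order], depth)
        rows.append(draw[inverse])
        kept_samples.append(sid)
    if not rows:
        raise NormalizationError(f"no sample reaches rarefaction depth {depth}")
    return AbundanceTable(kept_samples, list(table.taxon_ids), np.array(rows, dtype=float),
                          method="rarefied")


def _lower_quantile(sorted_vals: np.ndarray, q: float) -> float:
    """Type-1 (lower) empirical quantile of pre-sorted values."""
    n = len(sorted_vals)
    idx = max(int(np.ceil(q * n)) - 1, 0)
    return float(sorted_vals[idx])


def css_normalize(table: CountTable, quantile: float = 0.5) -> AbundanceTable:
    """Cumulative-sum scaling.

    Per sample j the scaling factor s_j is the sum of counts less than or
    equal to the q-th lower empirical quantile of that sample's nonzero
    counts; the output is counts / s_j * 1000.
    """
    if not 0 < quantile <= 1:
        raise ParameterError(f"quantile must lie in (0, 1], got {quantile}")
    out = np.empty(table.counts.shape, dtype=float)
    for i, sid in enumerate(table.sample_ids):
        row = table.counts[i]
        nonzero = np.sort(row[row > 0])
        if nonzero.size == 0:
            raise NormalizationError(f"sample {sid} has no positive counts")
        qval = _lower_quantile(nonzero, quantile)
        s = row[row <= qval].sum()
        if s == 0:
            raise NormalizationError(f"sample {sid}: CSS scaling factor is zero")
        out[i] = row / s * 1000.0
    return AbundanceTable(list(table.sample_ids), list(table.taxon_ids), out, method="css")


def to_relative(table: CountTable | AbundanceTable) -> AbundanceTable:
    values = table.values if isinstance(table, AbundanceTable) else table.counts
    sums = values.sum(axis=1, keepdims=True)
    if np.any(sums == 0):
        raise NormalizationError("cannot compute relative abundance of a zero row")
    return AbundanceTable(
        list(table.sample_ids), list(table.taxon_ids), values / sums, method="relative"
    )


def to_cpm(table: CountTable | AbundanceTable) -> AbundanceTable:
    rel = to_relative(table)
    return AbundanceTable(rel.sample_ids, rel.taxon_ids, rel.values * 1e6, method="cpm")


def aggregate_to_genus(table: CountTable, taxonomy: TaxonomyMap) -> CountTable:
    """Sum OTU counts sharing a genus label.

    OTUs unassigned at genus are labelled ``<lowest assigned rank>__unclassified``.
    """
    missing = [t for t in table.taxon_ids if t not in taxonomy]
    if missing:
        raise ValidationError(f"OTUs absent from taxonomy: {missing[:10]}")
    labels = [taxonomy.genus_label(t) for t in table.taxon_ids]
    genera = list(dict.fromkeys(labels))  # first-appearance order
    index = {g: i for i, g in enumerate(genera)}
    out = np.zeros((table.n_samples, len(genera)), dtype=np.int64)
    for col, g in enumerate(labels):
        out[:, index[g]] += table.counts[:, col]
    return CountTable(list(table.sample_ids), genera, out,
                      provenance=f"{table.provenance}|genus")


def aggregate_abundance_to_genus(table: AbundanceTable, taxonomy: TaxonomyMap) -> AbundanceTable:
    """Genus aggregation for real-valued tables (same labelling rules)."""
    missing = [t for t in table.taxon_ids if t not in taxonomy]
    if missing:
        raise ValidationError(f"taxa absent from taxonomy: {missing[:10]}")
    labels = [taxonomy.genus_label(t) for t in table.taxon_ids]
    genera = list(dict.fromkeys(labels))
    index = {g: i for i, g in enumerate(genera)}
    out = np.zeros((table.n_samples, len(genera)))
    for col, g in enumerate(labels):
        out[:, index[g]] += table.values[:, col]
    return AbundanceTable(list(table.sample_ids), genera, out, method=table.method)
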