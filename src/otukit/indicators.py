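"""Indicator-taxon (IndVal) analysis and focus-niche enrichment classification."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from otukit.normalize import AbundanceTable, to_cpm
from otukit.tables_io import CountTable, ValidationError


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


def _group_stats(values: np.ndarray, labels: np.ndarray, levels: np.ndarray):
    """Per-group mean abundance and presence fraction, groups x taxa."""
    means = np.vstack([values[labels == g].mean(axis=0) for g in levels])
    pres = np.vstack([(values[labels == g] > 0).mean(axis=0) for g in levels])
    return means, pres


def _indval_stats(values: np.ndarray, labels: np.ndarray, levels: np.ndarray) -> np.ndarray:
    """IndVal.g statistic sqrt(A*B) per group x taxon (NaN where undefined)."""
    means, pres = _group_stats(values, labels, levels)
    colsum = means.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(colsum > 0, means / colsum, np.nan)
    return np.sqrt(a * pres)


def indval(
    table: AbundanceTable | CountTable,
    groups,
    n_permutations: int = 999,
    seed: int = 0,
    stat_threshold: float = 0.6,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Single-group IndVal with a permutation test.

    For taxon t and group g, specificity A is the group mean abundance of t
    divided by the sum of group means (group-equalized), fidelity B is the
    fraction of g's samples where t occurs, and the statistic is
    sqrt(A * B). Each taxon is reported for its best single group; p is the
    add-one permutation tail probability of the best-group statistic under
    group-label shuffles. ``is_indicator`` flags taxa passing both the
    statistic and p thresholds.
    """
    values = table.values if isinstance(table, AbundanceTable) else table.counts.astype(float)
    labels = np.asarray(list(groups))
    if values.shape[0] != len(labels):
        raise ValidationError("group labels do not match table samples")
    levels, counts = np.unique(labels, return_counts=True)
    if len(levels) < 2 or counts.min() < 2:
        raise ValidationError("IndVal needs >= 2 groups with >= 2 samples each")

    means, pres = _group_stats(values, labels, levels)
    stats_obs = _indval_stats(values, labels, levels)
    active = means.sum(axis=0) > 0
    best_group = np.nanargmax(np.where(np.isnan(stats_obs), -1, stats_obs), axis=0)
    best_stat = np.where(active, stats_obs[best_group, np.arange(values.shape[1])], np.nan)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(values.shape[1])
    for _ in range(n_permutations):
        perm = rng.permutation(len(labels))
        stats_perm = _indval_stats(values[perm], labels, levels)
        best_perm = np.nanmax(np.where(np.isnan(stats_perm), -np.inf, stats_perm), axis=0)
        exceed += best_perm >= best_stat - 1e-12
    p = (1 + exceed) / (1 + n_permutations)

    cols = np.arange(values.shape[1])
    df = pd.DataFrame(
        {
            "taxon": table.taxon_ids,
            "group": [levels[g] for g in best_group],
            "A": means[best_group, cols] / np.where(active, means.sum(axis=0), np.nan),
            "B": pres[best_group, cols],
            "indval": best_stat,
            "p_value": np.where(active, p, np.nan),
        }
    ).set_index("taxon")
    df.loc[~active, ["group"]] = ""
    df["note"] = np.where(active, "", "all-zero taxon, skipped")
    df["is_indicator"] = (df["indval"] > stat_threshold) & (df["p_value"] < p_threshold)
    df["is_indicator"] = df["is_indicator"].fillna(False)
    return df


@dataclass
class EnrichmentSummary:
    n_enriched: int
    n_depleted: int
    n_unchanged: int


def classify_enrichment(
    table: CountTable,
    meta_groups,
    focus_group: str = "air",
    n_permutations: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Classify each OTU as enriched/depleted/unchanged in the focus group.

    Works on log2(CPM + 1). The statistic is mean(focus) - mean(others);
    p is a two-sided add-one permutation tail over sample-label shuffles,
    q is Benjamini-Hochberg across OTUs, and the class is decided by
    (q < alpha, sign of the log fold change).
    """
    labels = np.asarray(list(meta_groups))
    if labels.shape[0] != table.n_samples:
        raise ValidationError("group labels do not match table samples")
    focus = labels == focus_group
    if focus.sum() < 3 or (~focus).sum() < 3:
        raise ValidationError("focus group and complement each need >= 3 samples")
    present = table.counts.sum(axis=0) > 0
    x = np.log2(to_cpm(table).values + 1.0)

    n1 = int(focus.sum())
    n0 = int((~focus).sum())
    stat_obs = x[focus].mean(axis=0) - x[~focus].mean(axis=0)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(x.shape[1])
    for _ in range(n_permutations):
        perm_focus = np.zeros(len(labels), dtype=bool)
        perm_focus[rng.choice(len(labels), size=n1, replace=False)] = True
        stat_perm = x[perm_focus].mean(axis=0) - x[~perm_focus].mean(axis=0)
        exceed += np.abs(stat_perm) >= np.abs(stat_obs) - 1e-12
    p = (1 + exceed) / (1 + n_permutations)
    p = np.where(present, p, np.nan)

    q = np.full(x.shape[1], np.nan)
    q[present] = benjamini_hochberg(p[present])
    cpm = to_cpm(table).values
    logfc = np.log2(cpm[focus].mean(axis=0) + 1.0) - np.log2(cpm[~focus].mean(axis=0) + 1.0)
    classes = np.where(
        ~present, "absent",
        np.where(q >= alpha, "unchanged", np.where(logfc > 0, "enriched", "depleted")),
    )
    df = pd.DataFrame(
        {
            "taxon": table.taxon_ids,
            "mean_log_cpm": x.mean(axis=0),
            "logFC": logfc,
            "p_value": p,
            "q_value": q,
            "class": classes,
        }
    ).set_index("taxon")
    return df[df["class"] != "absent"]
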