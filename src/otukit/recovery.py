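"""Scoring of detected structure against planted synthetic ground truth."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from otukit.network import NetworkTopology
from otukit.synthetic import SyntheticTruth
from otukit.tables_io import TaxonomyMap


def evaluate_seed(seed: int, n_permutations: int = 999, spec_overrides: dict | None = None) -> dict:
    """Run the full detection pipeline on one synthetic dataset and score it.

    Returns per-seed recovery metrics: indicator sensitivity and
    false-positive rate, module ARI vs planted blocks, whether the planted
    hub ranks in the top-3 by betweenness, the fraction of blocks whose
    module majority-niche matches the planted niche, and the PERMANOVA
    p-value for the niche grouping.
    """
    from otukit import diversity, indicators, network, normalize, ordination
    from otukit.synthetic import SyntheticSpec, generate_dataset

    spec = SyntheticSpec(seed=seed, **(spec_overrides or {}))
    table, tax, meta, _, truth = generate_dataset(spec)
    niches = meta.niches(table.sample_ids)
    filtered = normalize.filter_rare_otus(table)

    rel = normalize.to_relative(filtered)
    iv = indicators.indval(rel, niches, n_permutations=n_permutations, seed=seed + 1)
    ind = score_indicators(iv, truth)

    genus = normalize.to_relative(normalize.aggregate_to_genus(filtered, tax))
    taxa = network.select_network_taxa(genus, niches=niches, scope="overall")
    rho, p = network.correlation_matrix(genus, taxa)
    g = network.build_network(rho, p)
    topo = network.topology(g, seed=seed + 2)
    pref = network.module_niche_preference(topo, genus, niches)

    css = normalize.css_normalize(filtered)
    dm = diversity.bray_curtis(css)
    perm = ordination.permanova(dm, niches, n_permutations=n_permutations, seed=seed + 3)

    return {
        "indicator_sensitivity": ind.sensitivity,
        "indicator_false_positive_rate": ind.false_positive_rate,
        "module_ari": score_modules(topo, truth, tax),
        "hub_in_top3": hub_in_top_k(network.keystones(topo, k=3), truth, tax),
        "module_majority_match": module_majority_match(pref, topo, truth, tax),
        "permanova_niche_p": perm.p_value,
    }


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Adjusted Rand index between two labelings of the same items."""
    a = pd.factorize(np.asarray(list(labels_a)))[0]
    b = pd.factorize(np.asarray(list(labels_b)))[0]
    if len(a) != len(b):
        raise ValueError("labelings differ in length")
    n = len(a)
    contingency = np.zeros((a.max() + 1, b.max() + 1), dtype=np.int64)
    np.add.at(contingency, (a, b), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(contingency).sum()
    sum_a = comb2(contingency.sum(axis=1)).sum()
    sum_b = comb2(contingency.sum(axis=0)).sum()
    total = comb2(n)
    expected = sum_a * sum_b / total if total > 0 else 0.0
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


@dataclass
class IndicatorRecovery:
    sensitivity: float          # planted indicators flagged / planted
    false_positive_rate: float  # non-planted flagged / non-planted
    n_planted: int
    n_flagged: int


def score_indicators(indval_df: pd.DataFrame, truth: SyntheticTruth) -> IndicatorRecovery:
    """Sensitivity and false-positive rate of indicator detection.

    A planted indicator counts as recovered only when it is flagged for its
    planted niche.
    """
    planted = truth.indicators
    flagged = indval_df[indval_df["is_indicator"]]
    hits = sum(
        1
        for taxon, niche in planted.items()
        if taxon in flagged.index and flagged.loc[taxon, "group"] == niche
    )
    negatives = [t for t in indval_df.index if t not in planted]
    false_pos = sum(1 for t in negatives if t in flagged.index)
    return IndicatorRecovery(
        sensitivity=hits / len(planted) if planted else float("nan"),
        false_positive_rate=false_pos / len(negatives) if negatives else float("nan"),
        n_planted=len(planted),
        n_flagged=int(len(flagged)),
    )


def _truth_on_nodes(truth_map: dict[str, int | str], nodes, translate=None) -> dict:
    if translate is not None:
        truth_map = {translate(t): v for t, v in truth_map.items()}
    return {n: truth_map[n] for n in nodes if n in truth_map}


def score_modules(
    topo: NetworkTopology, truth: SyntheticTruth, taxonomy: TaxonomyMap | None = None
) -> float:
    """ARI between detected modules and planted blocks, over planted taxa.

    Planted taxa missing from the network are assigned singleton modules
    (an honest penalty for non-recovery).
    """
    translate = taxonomy.genus_label if taxonomy is not None else None
    blocks = truth.blocks
    if translate is not None:
        blocks = {translate(t): b for t, b in blocks.items()}
    names = sorted(blocks)
    detected = []
    next_singleton = max(topo.modules.values(), default=0) + 1
    for name in names:
        if name in topo.modules:
            detected.append(topo.modules[name])
        else:
            detected.append(next_singleton)
            next_singleton += 1
    return adjusted_rand_index([blocks[n] for n in names], detected)


def hub_in_top_k(keystone_df: pd.DataFrame, truth: SyntheticTruth,
                 taxonomy: TaxonomyMap | None = None, k: int = 3) -> bool:
    if truth.hub is None:
        return False
    hub = taxonomy.genus_label(truth.hub) if taxonomy is not None else truth.hub
    return hub in keystone_df.head(k).index


def module_majority_match(
    module_pref: pd.DataFrame,
    topo: NetworkTopology,
    truth: SyntheticTruth,
    taxonomy: TaxonomyMap | None = None,
) -> float:
    """Fraction of planted blocks whose dominant detected module's majority
    niche equals the block's planted niche."""
    translate = taxonomy.genus_label if taxonomy is not None else (lambda t: t)
    matches, total = 0, 0
    for block, niche in truth.block_niches.items():
        members = [translate(t) for t, b in truth.blocks.items() if b == block]
        modules = [topo.modules[m] for m in members if m in topo.modules]
        if not modules:
            total += 1
            continue
        dominant = int(pd.Series(modules).mode().iloc[0])
        total += 1
        if dominant in module_pref.index and module_pref.loc[dominant, "majority_niche"] == niche:
            matches += 1
    return matches / total if total else float("nan")
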