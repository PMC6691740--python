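"""Synthetic community generator with planted, recoverable structure.

The generator produces a count table, taxonomy, metadata and tree that
mimic a multi-cave, four-niche survey design, together with a truth record
listing the planted indicator taxa, correlation blocks, hub taxon and
environmental-gradient taxa so downstream detection can be scored.

Latent model per sample ``s`` (niche ``n``, cave ``c``) and taxon ``t``::

    z_t(s) = mu_t + indicator_effect * [t indicator of n]
           + block_niche_effect * [t in a block preferring n]
           + gamma_{t,c} + sum_f beta_{t,f} * x_f(s) + u_t(s)

``u(s)`` is multivariate normal with block covariance: members of block k
correlate at ``block_rho`` through a shared factor, and the hub taxon loads
on the factors of ``hub_links`` blocks. Relative abundances are
``softmax(z)`` and counts are multinomial at the requested depth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import skbio

from otukit.tables_io import (
    NICHES,
    CountTable,
    PhyloTree,
    SampleMetadata,
    TaxonomyMap,
    ValidationError,
)

#: factors measured for every sample vs. only for some niches
_UNIVERSAL_FACTORS = ("depth_m", "temperature", "air_humidity")
_NICHE_FACTORS = {"pH": ("rock", "sediment"), "TOC": ("sediment", "water"),
                  "TN": ("sediment", "water"), "moisture": ("sediment",)}


class SpecError(ValueError):
    """A SyntheticSpec violates its own invariants."""


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic survey design."""

    n_caves: int = 8
    samples_per_cave_per_niche: int = 4
    n_taxa: int = 600
    depth: int = 30_000
    n_indicators_per_niche: int = 4
    indicator_effect: float = 2.0
    n_blocks: int = 4
    block_size: int = 12
    block_rho: float = 0.7
    block_niche_effect: float = 0.5
    hub_links: int = 2
    hub_coupling: float = 0.7
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"temperature": 0.5, "depth_m": 0.3}
    )
    n_gradient_taxa_per_factor: int = 10
    noise_sd: float = 1.0
    cave_sd: float = 0.3
    baseline_sd: float = 1.5
    block_abundance_boost: float = 3.0
    indicator_abundance_boost: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise SpecError("depth must be >= 1")
        if min(self.n_caves, self.samples_per_cave_per_niche, self.n_taxa) < 1:
            raise SpecError("counts must be positive")
        if not 0 <= self.block_rho < 1:
            raise SpecError("block_rho must lie in [0, 1)")
        if self.hub_links > self.n_blocks:
            raise SpecError("hub_links cannot exceed n_blocks")
        n_special = (
            self.n_blocks * self.block_size
            + (1 if self.n_blocks else 0)
            + self.n_indicators_per_niche * len(NICHES)
            + self.n_gradient_taxa_per_factor * len(self.covariate_effects)
        )
        if n_special > self.n_taxa:
            raise SpecError(
                f"planted structure needs {n_special} taxa but n_taxa={self.n_taxa}"
            )

    @property
    def n_samples(self) -> int:
        return self.n_caves * self.samples_per_cave_per_niche * len(NICHES)


@dataclass
class SyntheticTruth:
    """Ground-truth record of everything the generator planted."""

    indicators: dict[str, str]          # taxon -> target niche
    blocks: dict[str, int]              # taxon -> block id
    block_niches: dict[int, str]        # block id -> preferred niche
    hub: str | None
    gradient_taxa: dict[str, list[str]]  # factor -> affected taxa

    def to_json(self, path: str | Path) -> None:
        payload = {
            "indicators": self.indicators,
            "blocks": self.blocks,
            "block_niches": {str(k): v for k, v in self.block_niches.items()},
            "hub": self.hub,
            "gradient_taxa": self.gradient_taxa,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        raw = json.loads(Path(path).read_text())
        return cls(
            indicators=raw["indicators"],
            blocks={k: int(v) for k, v in raw["blocks"].items()},
            block_niches={int(k): v for k, v in raw["block_niches"].items()},
            hub=raw["hub"],
            gradient_taxa=raw["gradient_taxa"],
        )


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[CountTable, TaxonomyMap, SampleMetadata, PhyloTree, SyntheticTruth]:
    """Generate all five artifacts deterministically from ``spec.seed``."""
    root = np.random.SeedSequence(spec.seed)
    seeds = root.spawn(6)
    rng_assign = np.random.default_rng(seeds[0])
    rng_base = np.random.default_rng(seeds[1])
    rng_meta = np.random.default_rng(seeds[2])
    rng_noise = np.random.default_rng(seeds[3])
    rng_counts = np.random.default_rng(seeds[4])

    taxa = [f"OTU{i:04d}" for i in range(spec.n_taxa)]

    # ---- planted role assignment (disjoint) --------------------------------
    n_block_taxa = spec.n_blocks * spec.block_size
    n_hub = 1 if spec.n_blocks else 0
    n_ind = spec.n_indicators_per_niche * len(NICHES)
    factors = list(spec.covariate_effects)
    n_grad = spec.n_gradient_taxa_per_factor * len(factors)
    special = rng_assign.choice(spec.n_taxa, size=n_block_taxa + n_hub + n_ind + n_grad,
                                replace=False)
    pos = 0
    block_members: dict[int, np.ndarray] = {}
    for b in range(spec.n_blocks):
        block_members[b] = special[pos: pos + spec.block_size]
        pos += spec.block_size
    hub_idx = int(special[pos]) if n_hub else None
    pos += n_hub
    indicator_idx: dict[str, np.ndarray] = {}
    for niche in NICHES:
        indicator_idx[niche] = special[pos: pos + spec.n_indicators_per_niche]
        pos += spec.n_indicators_per_niche
    gradient_idx: dict[str, np.ndarray] = {}
    for f in factors:
        gradient_idx[f] = special[pos: pos + spec.n_gradient_taxa_per_factor]
        pos += spec.n_gradient_taxa_per_factor
    block_niches = {b: NICHES[b % len(NICHES)] for b in range(spec.n_blocks)}

    # ---- baseline log-abundance -------------------------------------------
    mu = rng_base.normal(0.0, spec.baseline_sd, size=spec.n_taxa)
    # block members (and the hub) are kept abundant with a tight baseline so
    # multinomial counting noise cannot wash out the planted correlations
    for members in block_members.values():
        mu[members] = rng_base.normal(spec.block_abundance_boost, 0.5, size=len(members))
    if hub_idx is not None:
        mu[hub_idx] = spec.block_abundance_boost + 0.5
    for idx in indicator_idx.values():
        mu[idx] += spec.indicator_abundance_boost

    # ---- sample design & metadata -----------------------------------------
    sample_ids, caves, niches = [], [], []
    for c in range(spec.n_caves):
        for niche in NICHES:
            for r in range(spec.samples_per_cave_per_niche):
                sample_ids.append(f"C{c + 1}_{niche}_{r + 1}")
                caves.append(f"C{c + 1}")
                niches.append(niche)
    n_samples = len(sample_ids)
    niches_arr = np.array(niches)
    caves_arr = np.array(caves)

    meta_frame = _draw_metadata(rng_meta, sample_ids, caves_arr, niches_arr, spec.n_caves)

    # ---- latent abundances -------------------------------------------------
    z = np.tile(mu, (n_samples, 1))  # samples x taxa
    for niche, idx in indicator_idx.items():
        z[np.ix_(niches_arr == niche, idx)] += spec.indicator_effect
    for b, members in block_members.items():
        z[np.ix_(niches_arr == block_niches[b], members)] += spec.block_niche_effect
    if spec.cave_sd > 0:
        gamma = rng_noise.normal(0.0, spec.cave_sd, size=(spec.n_caves, spec.n_taxa))
        # cave noise would dilute the planted block covariance, so the block
        # taxa and hub are exempt from it
        for members in block_members.values():
            gamma[:, members] = 0.0
        if hub_idx is not None:
            gamma[:, hub_idx] = 0.0
        cave_index = np.array([int(c[1:]) - 1 for c in caves_arr])
        z += gamma[cave_index, :]
    for f in factors:
        x = meta_frame[f].to_numpy(dtype=float)
        x = np.where(np.isnan(x), np.nanmean(x), x)
        x = (x - x.mean()) / (x.std() or 1.0)
        z[:, gradient_idx[f]] += spec.covariate_effects[f] * x[:, None]

    z += _block_noise(rng_noise, spec, n_samples, block_members, hub_idx)

    # ---- compositional counts ---------------------------------------------
    p = np.exp(z - z.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    counts = np.vstack([rng_counts.multinomial(spec.depth, p[i]) for i in range(n_samples)])
    # a zero row is astronomically unlikely at any realistic depth; guard anyway
    zero = counts.sum(axis=1) == 0
    if zero.any():
        counts[zero, 0] = 1

    table = CountTable(sample_ids, taxa, counts, provenance=f"synthetic(seed={spec.seed})")
    taxonomy = _make_taxonomy(rng_assign, spec, taxa, special)
    tree = generate_tree(taxa, seed=int(np.random.default_rng(seeds[5]).integers(2**32)))
    truth = SyntheticTruth(
        indicators={taxa[i]: n for n, idx in indicator_idx.items() for i in idx},
        blocks={taxa[i]: b for b, members in block_members.items() for i in members},
        block_niches=block_niches,
        hub=taxa[hub_idx] if hub_idx is not None else None,
        gradient_taxa={f: [taxa[i] for i in idx] for f, idx in gradient_idx.items()},
    )
    return table, taxonomy, SampleMetadata(meta_frame), tree, truth


def _block_noise(
    rng: np.random.Generator,
    spec: SyntheticSpec,
    n_samples: int,
    block_members: dict[int, np.ndarray],
    hub_idx: int | None,
) -> np.ndarray:
    """Idiosyncratic + block-factor noise with the planted covariance."""
    u = rng.normal(0.0, 1.0, size=(n_samples, spec.n_taxa))
    if spec.n_blocks and spec.block_rho > 0:
        # exact factor scores: orthonormalize the realized hub/block factor
        # vectors so the planted correlations hold in-sample, not just in
        # expectation (otherwise shared finite-sample luck moves every
        # hub-member correlation at once)
        raw = rng.normal(0.0, 1.0, size=(n_samples, spec.n_blocks + 1))
        raw -= raw.mean(axis=0)
        q, _ = np.linalg.qr(raw)
        factors = q * np.sqrt(n_samples)  # unit sample variance, orthogonal
        hub_factor = factors[:, 0]
        w = spec.hub_coupling
        for b, members in block_members.items():
            f = factors[:, b + 1]
            if b < spec.hub_links:  # blocks coupled to the hub share its factor
                f = np.sqrt(1.0 - w) * f + np.sqrt(w) * hub_factor
            u[:, members] = (
                np.sqrt(spec.block_rho) * f[:, None]
                + np.sqrt(1.0 - spec.block_rho) * u[:, members]
            )
        if hub_idx is not None:
            u[:, hub_idx] = hub_factor
    return spec.noise_sd * u


def _draw_metadata(
    rng: np.random.Generator,
    sample_ids: list[str],
    caves: np.ndarray,
    niches: np.ndarray,
    n_caves: int,
) -> pd.DataFrame:
    """Environmental factors drawn around realistic cave ranges.

    Temperature and humidity vary by cave with small site noise; pH, TOC,
    TN and moisture exist only for the niches where they are measured (NA
    elsewhere).
    """
    n = len(sample_ids)
    cave_temp = rng.uniform(11.0, 25.0, size=n_caves)
    cave_hum = rng.uniform(80.0, 91.0, size=n_caves)
    cave_no = np.array([int(c[1:]) - 1 for c in caves])
    frame = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    frame["cave_id"] = caves
    frame["niche"] = niches
    frame["depth_m"] = np.round(rng.uniform(5.0, 300.0, size=n), 1)
    frame["temperature"] = np.round(cave_temp[cave_no] + rng.normal(0, 0.5, size=n), 2)
    frame["air_humidity"] = np.round(
        np.clip(cave_hum[cave_no] + rng.normal(0, 1.0, size=n), 70, 100), 2
    )
    for factor, measured_in in _NICHE_FACTORS.items():
        if factor == "pH":
            vals = rng.uniform(7.9, 8.3, size=n)
        elif factor == "moisture":
            vals = rng.uniform(5.0, 40.0, size=n)
        else:  # TOC / TN, arbitrary but positive
            vals = rng.lognormal(0.0, 0.5, size=n)
        vals = np.round(vals, 3)
        frame[factor] = np.where(np.isin(niches, measured_in), vals, np.nan)
    return frame


def _make_taxonomy(
    rng: np.random.Generator, spec: SyntheticSpec, taxa: list[str], special: np.ndarray
) -> TaxonomyMap:
    """Synthetic 7-rank lineages.

    Planted taxa get a genus of their own (so genus aggregation cannot
    merge them); background taxa share genera from a pool, and a few are
    left unassigned at genus to exercise the fallback labelling.
    """
    n_phyla = 12
    phyla = [f"Phylum{chr(65 + i)}" for i in range(n_phyla)]
    n_genera = max(spec.n_taxa // 3, 1)
    genus_phylum = rng.integers(0, n_phyla, size=n_genera)
    special_set = set(int(i) for i in special)
    lineages: dict[str, tuple[str, ...]] = {}
    for i, taxon in enumerate(taxa):
        if i in special_set:
            g = f"Genus_{taxon}"
            ph = phyla[int(rng.integers(0, n_phyla))]
        else:
            gi = int(rng.integers(0, n_genera))
            ph = phyla[genus_phylum[gi]]
            g = f"Genus{gi:03d}"
        family = f"Family_{g}"
        if i not in special_set and rng.random() < 0.05:
            g = ""  # unassigned at genus; family is the lowest assigned rank
        lineages[taxon] = ("Bacteria", ph, f"Class_{ph}", f"Order_{ph}", family, g, "")
    return TaxonomyMap(lineages)


def generate_tree(taxon_ids: list[str], seed: int = 0) -> PhyloTree:
    """Random binary rooted tree over ``taxon_ids`` by sequential random joins.

    Branch lengths are exponential(1) draws.
    """
    ids = list(taxon_ids)
    if len(ids) < 2:
        raise SpecError("need at least 2 taxa to build a tree")
    rng = np.random.default_rng(seed)
    nodes = [skbio.TreeNode(name=t, length=float(rng.exponential(1.0))) for t in ids]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        i, j = sorted((int(i), int(j)))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = skbio.TreeNode(length=float(rng.exponential(1.0)), children=[left, right])
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return PhyloTree(root)
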