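"""Config-driven orchestration of the full analysis workflow.

Stages: rare-OTU filter -> rarefy/CSS -> alpha -> beta -> PCoA -> PERMANOVA
-> envfit -> rank-correlation screen -> Venn -> Sorensen partition ->
IndVal -> enrichment -> genus aggregation -> co-occurrence networks
(overall + per niche) -> topology -> keystones -> module-niche preference.
All randomness derives from one root seed via stable per-stage hashing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from otukit import diversity, indicators, network, normalize, ordination, recovery
from otukit.synthetic import SyntheticSpec, SyntheticTruth, generate_dataset
from otukit.tables_io import (
    NICHES,
    CountTable,
    PhyloTree,
    SampleMetadata,
    TaxonomyMap,
    read_count_table,
    read_metadata,
    read_newick,
    read_taxonomy,
    write_count_table,
    write_frame,
    write_metadata,
    write_network,
    write_taxonomy,
)

logger = logging.getLogger(__name__)


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed from the root seed."""
    digest = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % (2**32)


@dataclass
class RunConfig:
    """All knobs of a pipeline run; mirrors the YAML config layout."""

    out_dir: str = "otukit_run"
    seed: int = 0
    # inputs: either file paths or a synthetic spec
    counts: str | None = None
    taxonomy: str | None = None
    metadata: str | None = None
    tree: str | None = None
    truth: str | None = None
    orientation: str = "taxa_rows"
    synthetic: dict | None = None
    # analysis parameters
    rare_otu_threshold: float = 1e-5
    rarefaction_depth: int | None = None
    css_quantile: float = 0.5
    beta_metric: str = "braycurtis"  # or "wunifrac"
    n_permutations: int = 999
    envfit_axes: int = 2
    env_variables: list[str] = field(
        default_factory=lambda: ["depth_m", "temperature", "air_humidity", "pH",
                                 "TOC", "TN", "moisture"]
    )
    indval_stat_threshold: float = 0.6
    indval_p_threshold: float = 0.05
    enrich_focus: str = "air"
    enrich_n_permutations: int = 2000
    network_rho_min: float = 0.6
    network_p_max: float = 0.01
    network_abundance_threshold: float = 0.0005
    network_fdr: bool = True
    network_scopes: list[str] = field(default_factory=lambda: ["overall", *NICHES])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def load_inputs(
    cfg: RunConfig,
) -> tuple[CountTable, TaxonomyMap | None, SampleMetadata | None, PhyloTree | None,
           SyntheticTruth | None]:
    if cfg.synthetic is not None:
        spec = SyntheticSpec(**{**cfg.synthetic, "seed": cfg.synthetic.get("seed", cfg.seed)})
        table, tax, meta, tree, truth = generate_dataset(spec)
        return table, tax, meta, tree, truth
    if cfg.counts is None:
        raise ValueError("config needs either 'counts' or a 'synthetic' block")
    table = read_count_table(cfg.counts, orientation=cfg.orientation)
    tax = read_taxonomy(cfg.taxonomy) if cfg.taxonomy else None
    meta = read_metadata(cfg.metadata) if cfg.metadata else None
    tree = read_newick(cfg.tree, expected_taxa=table.taxon_ids) if cfg.tree else None
    truth = SyntheticTruth.from_json(cfg.truth) if cfg.truth else None
    return table, tax, meta, tree, truth


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage, write artifacts under ``cfg.out_dir``, return the report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    report: dict = {"seed": cfg.seed, "stages": {}}

    def save_frame(df: pd.DataFrame, name: str, index: bool = True) -> None:
        path = out / name
        write_frame(df, path, index=index)
        manifest[name] = str(path)

    def timed(stage: str):
        t0 = time.perf_counter()

        def done():
            report["stages"][stage] = round(time.perf_counter() - t0, 3)
            logger.info("stage %s: %.2fs", stage, report["stages"][stage])

        return done

    # ---- inputs ------------------------------------------------------------
    done = timed("load")
    table, tax, meta, tree, truth = load_inputs(cfg)
    if meta is not None:
        meta.check_covers(table)
    if cfg.synthetic is not None:
        write_count_table(table, out / "counts.tsv")
        manifest["counts.tsv"] = str(out / "counts.tsv")
        if tax:
            write_taxonomy(tax, out / "taxonomy.tsv")
            manifest["taxonomy.tsv"] = str(out / "taxonomy.tsv")
        if meta is not None:
            write_metadata(meta, out / "metadata.tsv")
            manifest["metadata.tsv"] = str(out / "metadata.tsv")
        if tree is not None:
            tree.write(out / "tree.nwk")
            manifest["tree.nwk"] = str(out / "tree.nwk")
        if truth is not None:
            truth.to_json(out / "truth.json")
            manifest["truth.json"] = str(out / "truth.json")
    done()

    # ---- filtering and normalization --------------------------------------
    done = timed("normalize")
    filtered = normalize.filter_rare_otus(table, cfg.rare_otu_threshold)
    rarefied = normalize.rarefy(filtered, cfg.rarefaction_depth,
                                seed=stage_seed(cfg.seed, "rarefy"))
    css = normalize.css_normalize(filtered, cfg.css_quantile)
    relative = normalize.to_relative(filtered)
    done()

    # ---- alpha diversity ---------------------------------------------------
    done = timed("alpha")
    alpha = diversity.alpha_table(rarefied)
    save_frame(alpha, "alpha.tsv")
    done()

    # ---- beta diversity ----------------------------------------------------
    done = timed("beta")
    if cfg.beta_metric == "wunifrac":
        if tree is None:
            raise ValueError("beta_metric=wunifrac requires a tree input")
        dm = diversity.weighted_unifrac(css, tree, normalized=True)
    else:
        dm = diversity.bray_curtis(css)
    save_frame(dm.to_frame(), "beta_distances.tsv")
    done()

    # ---- ordination + tests ------------------------------------------------
    done = timed("ordination")
    ordi = ordination.pcoa(dm)
    coords = pd.DataFrame(
        ordi.coordinates[:, : max(2, cfg.envfit_axes)],
        index=ordi.sample_ids,
        columns=[f"PC{i + 1}" for i in range(ordi.coordinates[:, : max(2, cfg.envfit_axes)].shape[1])],
    )
    save_frame(coords, "pcoa_coordinates.tsv")
    done()

    permanova_rows = []
    envfit_rows = []
    screen = None
    venn = None
    if meta is not None:
        done = timed("permanova")
        niches = meta.niches(table.sample_ids)
        caves = meta.caves(table.sample_ids)
        for name, labels in (("niche", niches), ("cave", caves)):
            res = ordination.permanova(
                dm, labels, n_permutations=cfg.n_permutations,
                seed=stage_seed(cfg.seed, f"permanova:{name}"), grouping_name=name,
            )
            permanova_rows.append(dataclasses.asdict(res))
        save_frame(pd.DataFrame(permanova_rows).set_index("grouping"), "permanova.tsv")
        done()

        done = timed("envfit")
        for var in cfg.env_variables:
            if var not in meta.frame.columns:
                continue
            ids, vals = meta.variable(var, table.sample_ids)
            if len(ids) < 4 or np.ptp(vals) == 0:
                continue
            res = ordination.envfit(
                ordi, vals, variable=var, k_axes=cfg.envfit_axes,
                n_permutations=cfg.n_permutations,
                seed=stage_seed(cfg.seed, f"envfit:{var}"), sample_ids=ids,
            )
            envfit_rows.append(
                {"variable": var, "r2": res.r2, "p_value": res.p_value, "n": res.n,
                 **{f"axis{i + 1}": c for i, c in enumerate(res.direction)}}
            )
        if envfit_rows:
            save_frame(pd.DataFrame(envfit_rows).set_index("variable"), "envfit.tsv")
        done()

        done = timed("corr_screen")
        screen = ordination.rank_correlation_screen(
            alpha, meta, [v for v in cfg.env_variables if v in meta.frame.columns]
        )
        save_frame(screen, "shannon_correlations.tsv")
        done()

        done = timed("venn")
        venn_raw = diversity.venn_counts(filtered, dict(zip(table.sample_ids, niches)))
        venn = {"+".join(sorted(k)): v for k, v in venn_raw.items()}
        (out / "venn.json").write_text(json.dumps(venn, indent=2))
        manifest["venn.json"] = str(out / "venn.json")
        done()

        done = timed("beta_partition")
        partition = diversity.beta_partition_table(filtered)
        save_frame(partition, "beta_partition.tsv", index=False)
        done()

        done = timed("indval")
        indval_df = indicators.indval(
            relative, niches, n_permutations=cfg.n_permutations,
            seed=stage_seed(cfg.seed, "indval"),
            stat_threshold=cfg.indval_stat_threshold, p_threshold=cfg.indval_p_threshold,
        )
        save_frame(indval_df, "indval.tsv")
        done()

        done = timed("enrichment")
        enrich_df = indicators.classify_enrichment(
            filtered, niches, focus_group=cfg.enrich_focus,
            n_permutations=cfg.enrich_n_permutations,
            seed=stage_seed(cfg.seed, "enrich"),
        )
        save_frame(enrich_df, "enrichment.tsv")
        done()

    # ---- co-occurrence networks -------------------------------------------
    network_reports = {}
    if tax is not None and meta is not None:
        done = timed("network")
        genus_counts = normalize.aggregate_to_genus(filtered, tax)
        genus_rel = normalize.to_relative(genus_counts)
        niches = meta.niches(table.sample_ids)
        phylum_of = {
            g: next(
                (tax.rank(t, "phylum") for t in filtered.taxon_ids
                 if tax.genus_label(t) == g), ""
            )
            for g in genus_rel.taxon_ids
        }
        for scope in cfg.network_scopes:
            if scope == "overall":
                sub_rel = genus_rel
                sub_niches = niches
            else:
                mask = niches == scope
                keep = [s for s, m in zip(genus_rel.sample_ids, mask) if m]
                idx = [genus_rel.sample_ids.index(s) for s in keep]
                sub_rel = normalize.AbundanceTable(
                    keep, list(genus_rel.taxon_ids), genus_rel.values[idx], "relative"
                )
                sub_niches = niches[mask]
            taxa = network.select_network_taxa(
                sub_rel, niches=sub_niches, scope="overall",
                threshold=cfg.network_abundance_threshold,
            )
            if len(taxa) < 2:
                continue
            rho, p = network.correlation_matrix(sub_rel, taxa)
            g = network.build_network(
                rho, p, rho_min=cfg.network_rho_min, p_max=cfg.network_p_max,
                fdr=cfg.network_fdr, node_attrs={"phylum": phylum_of},
            )
            if g.number_of_edges() == 0:
                network_reports[scope] = {"nodes": 0, "edges": 0}
                continue
            topo = network.topology(g, seed=stage_seed(cfg.seed, f"louvain:{scope}"))
            nxmod = {n: int(m) for n, m in topo.modules.items()}
            bc = topo.betweenness
            import networkx as nx

            nx.set_node_attributes(g, nxmod, "module")
            nx.set_node_attributes(g, bc, "betweenness")
            write_network(g, out / f"network_{scope}")
            manifest[f"network_{scope}.graphml"] = str(out / f"network_{scope}.graphml")
            keystone_df = network.keystones(topo, k=3)
            save_frame(keystone_df, f"keystones_{scope}.tsv")
            pref = network.module_niche_preference(topo, genus_rel, niches)
            save_frame(pref, f"module_niche_{scope}.tsv")
            network_reports[scope] = topo.to_json_dict()
            network_reports[scope]["keystones"] = list(keystone_df.index)
        done()

    # ---- truth recovery ----------------------------------------------------
    recovery_report = None
    if truth is not None and meta is not None and tax is not None:
        done = timed("recovery")
        ind_rec = recovery.score_indicators(indval_df, truth)
        overall_topo = None
        if "overall" in network_reports and network_reports["overall"].get("edges"):
            # recompute topology objects for scoring on the overall scope
            taxa = network.select_network_taxa(
                genus_rel, niches=niches, scope="overall",
                threshold=cfg.network_abundance_threshold,
            )
            rho, p = network.correlation_matrix(genus_rel, taxa)
            g = network.build_network(rho, p, rho_min=cfg.network_rho_min,
                                      p_max=cfg.network_p_max, fdr=cfg.network_fdr)
            overall_topo = network.topology(g, seed=stage_seed(cfg.seed, "louvain:overall"))
        recovery_report = {
            "indicator_sensitivity": ind_rec.sensitivity,
            "indicator_false_positive_rate": ind_rec.false_positive_rate,
        }
        if overall_topo is not None:
            pref = network.module_niche_preference(overall_topo, genus_rel, niches)
            recovery_report["module_ari"] = recovery.score_modules(overall_topo, truth, tax)
            recovery_report["hub_in_top3"] = recovery.hub_in_top_k(
                network.keystones(overall_topo, k=3), truth, tax
            )
            recovery_report["module_majority_match"] = recovery.module_majority_match(
                pref, overall_topo, truth, tax
            )
        if permanova_rows:
            recovery_report["permanova_niche_p"] = next(
                r["p_value"] for r in permanova_rows if r["grouping"] == "niche"
            )
        done()

    report.update(
        {
            "manifest": manifest,
            "n_samples": table.n_samples,
            "n_taxa_input": table.n_taxa,
            "n_taxa_filtered": filtered.n_taxa,
            "permanova": permanova_rows,
            "envfit": envfit_rows,
            "venn_total_shared": venn.get("+".join(sorted(set(NICHES)))) if venn else None,
            "networks": network_reports,
            "recovery": recovery_report,
        }
    )
    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
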