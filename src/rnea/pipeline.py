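"""End-to-end orchestration: parse -> classify -> enrich -> extract -> write.

A single :func:`run_pipeline` call reproduces the whole analysis from a DE
table and reference interaction files, emitting ranked enrichment tables
(CSV and/or sortable HTML), the extracted subnetwork in Cytoscape-ready
TSV form, and a machine-readable JSON manifest of the run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .de import classify, parse_de_table
from .enrichment import run_all
from .network import (GeneSetCollection, ReferenceNetwork, load_alias_map,
                      load_gene_sets, load_interactions)
from .report import write_csv, write_html
from .subnetwork import (Subnetwork, extract_functional, extract_global,
                         extract_regulatory, write_subnetwork)

logger = logging.getLogger(__name__)

NETWORK_MODES = ("regulatory", "functional", "global")
OUTPUT_FORMATS = ("html", "csv", "both")


@dataclass
class RunConfig:
    """Everything one pipeline run needs; defaults mirror common usage."""

    de_table: str
    interactions: str
    mirna_interactions: str | None = None
    gene_set_files: list[tuple[str, str]] = field(default_factory=list)
    # ^ (path, category_type) pairs, category_type in {GO, KEGG, custom}
    out_dir: str = "rnea_output"
    species_label: str = ""
    identifier: str = "GeneName"          # GeneName | Refseq
    alias_file: str | None = None
    network_mode: str = "regulatory"
    output_format: str = "csv"
    fc_threshold: float = 1.0
    p_threshold: float = 0.05
    alpha: float = 0.05                   # subnetwork-inclusion cutoff (p_adj)
    seed_mode: str = "de"
    universe_policy: str = "measured"
    first_level_only: bool = False
    column_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.network_mode not in NETWORK_MODES:
            raise ValueError(f"network_mode must be one of {NETWORK_MODES}")
        if self.output_format not in OUTPUT_FORMATS:
            raise ValueError(f"output_format must be one of {OUTPUT_FORMATS}")
        if self.identifier not in ("GeneName", "Refseq"):
            raise ValueError("identifier must be GeneName or Refseq")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the run manifest (also written).

    Stages: DE parsing, threshold classification, two-level profile
    construction, the nine (or fewer) enrichment tables, subnetwork
    extraction in the configured mode, and deterministic writers.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        logger.info("stage: %s", name)

    stage("parse")
    alias = load_alias_map(config.alias_file) if config.alias_file else None
    profile = parse_de_table(config.de_table, column_map=config.column_map,
                             alias_map=alias)
    stage("classify")
    profile = classify(profile, config.fc_threshold, config.p_threshold)

    stage("load networks")
    net = load_interactions(config.interactions, "TF",
                            species_label=config.species_label)
    mirna_net: ReferenceNetwork | None = None
    if config.mirna_interactions:
        mirna_net = load_interactions(config.mirna_interactions, "miRNA",
                                      species_label=config.species_label)
    gene_sets: list[GeneSetCollection] = [
        load_gene_sets(path, ctype) for path, ctype in config.gene_set_files]

    stage("enrichment")
    tables = run_all(net, mirna_net, gene_sets, profile,
                     universe_policy=config.universe_policy,
                     first_level_only=config.first_level_only)

    table_files: dict[str, dict[str, str]] = {}
    table_rows: dict[str, int] = {}
    for (ctype, part), results in sorted(tables.items()):
        key = f"{ctype}_{part}"
        table_rows[key] = len(results)
        files = {}
        if config.output_format in ("csv", "both"):
            files["csv"] = str(write_csv(results, out / f"enrichment_{key}.csv"))
        if config.output_format in ("html", "both"):
            files["html"] = str(write_html(
                results, out / f"enrichment_{key}.html",
                title=f"{ctype} enrichment — {part} partition"))
        table_files[key] = files

    stage(f"extract ({config.network_mode})")
    regulatory: Subnetwork | None = None
    functional: Subnetwork | None = None
    if config.network_mode in ("regulatory", "global"):
        regulatory = extract_regulatory(
            net, mirna_net, profile, enrichments=tables,
            seed_mode=config.seed_mode, alpha=config.alpha)
    if config.network_mode in ("functional", "global"):
        functional = extract_functional(gene_sets, tables, profile,
                                        alpha=config.alpha)
    if config.network_mode == "global":
        sub = extract_global(regulatory, functional)
    else:
        sub = regulatory if regulatory is not None else functional

    stage("write subnetwork")
    edge_path, node_path = write_subnetwork(
        sub, out / f"subnetwork_{config.network_mode}.tsv")

    manifest = {
        "version": __version__,
        "inputs": {
            "de_table": str(config.de_table),
            "interactions": str(config.interactions),
            "mirna_interactions": config.mirna_interactions,
            "gene_sets": [list(gs) for gs in config.gene_set_files],
        },
        "parameters": {
            "fc_threshold": config.fc_threshold,
            "p_threshold": config.p_threshold,
            "alpha": config.alpha,
            "seed_mode": config.seed_mode,
            "network_mode": config.network_mode,
            "universe_policy": config.universe_policy,
            "identifier": config.identifier,
            "species": config.species_label,
        },
        "counts": {
            "measured_genes": len(profile.records),
            "de_genes": len(profile.de_genes),
            "up_genes": len(profile.up_genes),
            "down_genes": len(profile.down_genes),
            "reference_interactions": len(net),
            "mirna_interactions": len(mirna_net) if mirna_net else 0,
            "enrichment_tables": len(tables),
            "table_rows": table_rows,
            "subnetwork_edges": len(sub),
            "subnetwork_nodes": len(sub.nodes),
            "hidden_intermediates": len(sub.hidden_intermediates),
        },
        "outputs": {
            "tables": table_files,
            "subnetwork_edges": str(edge_path),
            "subnetwork_nodes": str(node_path),
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n",
        encoding="utf-8")
    return manifest
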