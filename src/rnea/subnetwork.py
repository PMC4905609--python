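"""Active-subnetwork extraction from the reference regulatory network.

Starting from seed regulators, a subset of the reference "super-network"
is traced with three inclusion rules applied over each seed's two-level
profile:

R1  a seed regulator is included as a node when it is deregulated;
R2  an edge regulator->t is included when the first-level target t is
    deregulated (and, for deregulated targets that are themselves
    regulators, their own edges to deregulated daughters);
R3  a first-level target t that is NOT deregulated is still included —
    as a *hidden intermediate* — when its parent regulator and one of its
    own daughter targets are both deregulated; both edges of the
    regulator->t->daughter chain enter the subnetwork.

Rule 3 surfaces a hidden layer of regulation: a regulator whose
transcript was not measured as changed but whose upstream driver and
downstream consequence both were.  Seeds default to deregulated
regulators; enrichment-driven seeding (target-set adjusted p <= alpha)
is available, and miRNA regulators — absent from an mRNA profile — are
seeded by enrichment only.

Functional mode connects enriched GO/KEGG categories to their deregulated
members; global mode is the union of the two.  Output is a Cytoscape-ready
tab-separated edge table plus a node-attribute table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

from .de import DEProfile
from .enrichment import (EnrichmentResult, build_profiles,
                         significant_categories)
from .network import GeneSetCollection, ReferenceNetwork

R1, R2, R3 = "R1_regulator_de", "R2_target_de", "R3_hidden_intermediate"
_RULE_PRIORITY = {R2: 0, R3: 1, R1: 2}  # lower wins on duplicate edges

TF_TARGET, MIRNA_TARGET, CATEGORY_MEMBER = (
    "TF_target", "miRNA_target", "category_member")

SEED_MODES = ("de", "enriched", "union")


@dataclass(frozen=True)
class NodeInfo:
    node_type: str          # TF | miRNA | gene | GO | KEGG | custom
    status: str             # up | down | unchanged | unmeasured
    hidden: bool = False    # rule-3 hidden intermediate


@dataclass
class Subnetwork:
    """Edge list with rule annotations plus per-node type/status."""

    edges: dict[tuple[str, str, str], str] = field(default_factory=dict)
    nodes: dict[str, NodeInfo] = field(default_factory=dict)

    def add_edge(self, source: str, target: str, kind: str, rule: str) -> None:
        key = (source, target, kind)
        old = self.edges.get(key)
        if old is None or _RULE_PRIORITY[rule] < _RULE_PRIORITY[old]:
            self.edges[key] = rule

    def add_node(self, node: str, node_type: str, status: str,
                 hidden: bool = False) -> None:
        old = self.nodes.get(node)
        if old is None:
            self.nodes[node] = NodeInfo(node_type, status, hidden)
        elif hidden and not old.hidden:
            self.nodes[node] = replace(old, hidden=True)

    @property
    def hidden_intermediates(self) -> set[str]:
        return {n for n, info in self.nodes.items() if info.hidden}

    def edge_set(self) -> set[tuple[str, str, str, str]]:
        return {(s, t, k, r) for (s, t, k), r in self.edges.items()}

    def __len__(self) -> int:
        return len(self.edges)


def _node_type(node: str, tf_regs: set[str], mirna_regs: set[str]) -> str:
    if node in tf_regs:
        return "TF"
    if node in mirna_regs:
        return "miRNA"
    return "gene"


def _seed_regulators(net: ReferenceNetwork, profile: DEProfile,
                     enrichments, seed_mode: str, alpha: float) -> set[str]:
    regs = net.regulators
    de_seeds = {r for r in regs if profile.status_of(r) in ("up", "down")}
    if seed_mode == "de":
        return de_seeds
    if enrichments is None:
        raise ValueError(f"seed_mode={seed_mode!r} requires enrichment results")
    enr_seeds: set[str] = set()
    for (ctype, _part), results in enrichments.items():
        if ctype == "TF":
            enr_seeds |= significant_categories(results, alpha)
    enr_seeds &= regs
    if seed_mode == "enriched":
        return enr_seeds
    if seed_mode == "union":
        return de_seeds | enr_seeds
    raise ValueError(f"unknown seed_mode {seed_mode!r}")


def extract_regulatory(net: ReferenceNetwork,
                       mirna_net: ReferenceNetwork | None,
                       profile: DEProfile,
                       enrichments: dict[tuple[str, str],
                                         list[EnrichmentResult]] | None = None,
                       seed_mode: str = "de",
                       alpha: float = 0.05) -> Subnetwork:
    """Trace the active regulatory subnetwork via the three inclusion rules.

    For each seed regulator R with two-level profile over the reference
    network: deregulated first-level targets t give edges R->t (rule 2),
    and when such a t is itself a regulator its edges t->d to deregulated
    daughters join too; non-deregulated first-level targets with a
    deregulated daughter give the full R->t->d chain (rule 3) and t is
    flagged hidden.  Enriched miRNAs contribute first-level edges to
    deregulated targets.  Duplicate edges keep the highest-priority rule
    (R2 > R3 > R1).
    """
    if seed_mode not in SEED_MODES:
        raise ValueError(f"unknown seed_mode {seed_mode!r}")
    sub = Subnetwork()
    tf_regs = net.regulators
    mirna_regs = mirna_net.regulators if mirna_net is not None else set()

    def put_node(node: str, hidden: bool = False) -> None:
        sub.add_node(node, _node_type(node, tf_regs, mirna_regs),
                     profile.status_of(node), hidden)

    profiles = build_profiles(net)
    seeds = _seed_regulators(net, profile, enrichments, seed_mode, alpha)
    is_de = profile.de_genes

    for reg in sorted(seeds):
        put_node(reg)  # R1: the seed regulator itself
        prof = profiles[reg]
        daughters: dict[str, set[str]] = {}
        for t, d in prof.second_level:
            daughters.setdefault(t, set()).add(d)
        for t in prof.first_level:
            if t in is_de:
                sub.add_edge(reg, t, TF_TARGET, R2)
                put_node(t)
                for d in daughters.get(t, ()):  # the Regulator-B-B2 chain
                    if d in is_de:
                        sub.add_edge(t, d, TF_TARGET, R2)
                        put_node(d)
            elif reg in is_de:
                # rule 3 demands a deregulated parent: under enrichment
                # seeding a non-DE seed cannot spawn hidden chains
                de_daughters = daughters.get(t, set()) & is_de
                if de_daughters:
                    sub.add_edge(reg, t, TF_TARGET, R3)
                    put_node(t, hidden=True)
                    for d in de_daughters:
                        sub.add_edge(t, d, TF_TARGET, R3)
                        put_node(d)

    if mirna_net is not None and enrichments is not None:
        enr_mirnas: set[str] = set()
        for (ctype, _part), results in enrichments.items():
            if ctype == "miRNA":
                enr_mirnas |= significant_categories(results, alpha)
        for m in sorted(enr_mirnas & mirna_regs):
            de_targets = mirna_net.targets_of(m) & is_de
            if not de_targets:
                continue
            put_node(m)
            for t in de_targets:
                sub.add_edge(m, t, MIRNA_TARGET, R2)
                put_node(t)
    return sub


def extract_functional(gene_sets: list[GeneSetCollection],
                       enrichments: dict[tuple[str, str],
                                         list[EnrichmentResult]],
                       profile: DEProfile,
                       alpha: float = 0.05) -> Subnetwork:
    """Enriched functional categories connected to their deregulated members.

    A category node appears when its adjusted p-value passes alpha in any
    partition; edges run category->gene for each deregulated member in
    the universe.
    """
    sub = Subnetwork()
    is_de = profile.de_genes
    for coll in gene_sets:
        enriched: set[str] = set()
        for part in ("all", "up", "down"):
            results = enrichments.get((coll.category_type, part), [])
            enriched |= significant_categories(results, alpha)
        for cid in sorted(enriched & set(coll.sets)):
            members = coll.sets[cid][1] & profile.universe & is_de
            if not members:
                continue
            sub.add_node(cid, coll.category_type, "unmeasured")
            for g in members:
                sub.add_edge(cid, g, CATEGORY_MEMBER, R2)
                sub.add_node(g, "gene", profile.status_of(g))
    return sub


def extract_global(regulatory: Subnetwork, functional: Subnetwork) -> Subnetwork:
    """Node- and edge-wise union of the regulatory and functional views."""
    merged = Subnetwork()
    for src in (regulatory, functional):
        for (s, t, kind), rule in src.edges.items():
            merged.add_edge(s, t, kind, rule)
        for node, info in src.nodes.items():
            merged.add_node(node, info.node_type, info.status, info.hidden)
    return merged


_EDGE_HEADER = ("source", "interaction", "target", "rule", "source_status",
                "target_status", "source_type", "target_type")
_NODE_HEADER = ("node", "node_type", "status", "hidden", "degree")


def write_subnetwork(sub: Subnetwork, path: str | Path) -> tuple[Path, Path]:
    """Write the edge table TSV plus a companion node-attribute TSV.

    Rows are sorted by (source, target, interaction) for determinism, so
    identical runs produce byte-identical files.  Returns both paths; the
    node file sits next to the edge file with a ``.nodes.tsv`` suffix.
    The tab-separated layout loads directly into Cytoscape-style network
    visualisation tools.
    """
    path = Path(path)
    node_path = path.with_suffix("").with_suffix(".nodes.tsv") \
        if path.suffix == ".tsv" else Path(str(path) + ".nodes.tsv")
    degree: dict[str, int] = {n: 0 for n in sub.nodes}
    for s, t, _ in sub.edges:
        degree[s] = degree.get(s, 0) + 1
        degree[t] = degree.get(t, 0) + 1
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_EDGE_HEADER) + "\n")
        for (s, t, kind) in sorted(sub.edges):
            rule = sub.edges[(s, t, kind)]
            s_info = sub.nodes[s]
            t_info = sub.nodes[t]
            fh.write(f"{s}\t{kind}\t{t}\t{rule}\t{s_info.status}\t"
                     f"{t_info.status}\t{s_info.node_type}\t"
                     f"{t_info.node_type}\n")
    with open(node_path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_NODE_HEADER) + "\n")
        for node in sorted(sub.nodes):
            info = sub.nodes[node]
            fh.write(f"{node}\t{info.node_type}\t{info.status}\t"
                     f"{'yes' if info.hidden else 'no'}\t{degree[node]}\n")
    return path, node_path


def read_subnetwork(edge_path: str | Path,
                    node_path: str | Path | None = None) -> Subnetwork:
    """Reload a written subnetwork (round-trips with write_subnetwork)."""
    edge_path = Path(edge_path)
    if node_path is None:
        node_path = edge_path.with_suffix("").with_suffix(".nodes.tsv")
    sub = Subnetwork()
    with open(node_path, encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            node, ntype, status, hidden, _deg = line.rstrip("\n").split("\t")
            sub.add_node(node, ntype, status, hidden == "yes")
    with open(edge_path, encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            s, kind, t, rule, *_ = line.rstrip("\n").split("\t")
            sub.add_edge(s, t, kind, rule)
    return sub
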