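"""Reference regulatory network and gene-set collection data model and I/O.

A reference network is a deduplicated set of directed regulator->target
interactions compiled from curated resources.  Each interaction records
whether the regulator is a transcription factor (TF) or a miRNA, plus
free-text provenance.  Gene-set collections (GO terms, KEGG pathways or
custom categories) are read from standard GMT files.

File dialect for interaction flat files: tab-separated columns

    regulator  target  [type]  [sources]  [evidence]

where ``type`` is ``TF`` or ``miRNA``, ``sources`` is comma-joined, and
lines starting with ``#`` are comments.  Identifiers are opaque,
case-sensitive strings; an optional two-column alias file (alias, canonical)
supports switching between gene-symbol and RefSeq naming.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

REGULATOR_TYPES = ("TF", "miRNA")

CATEGORY_TYPES = ("GO", "KEGG", "custom")


@dataclass
class Interaction:
    """One directed regulator->target edge with provenance."""

    regulator: str
    target: str
    regulator_type: str = "TF"
    sources: set[str] = field(default_factory=set)
    evidence: str = ""

    def __post_init__(self) -> None:
        if not self.regulator or not self.target:
            raise ValueError("regulator and target must be non-empty strings")
        if self.regulator_type not in REGULATOR_TYPES:
            raise ValueError(
                f"regulator_type must be one of {REGULATOR_TYPES}, "
                f"got {self.regulator_type!r}"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.regulator, self.target, self.regulator_type)


class ReferenceNetwork:
    """Deduplicated set of regulatory interactions with derived indices.

    Interactions sharing (regulator, target, regulator_type) are merged by
    taking the union of their sources.  Self-edges (autoregulation) are
    stored like any other edge.
    """

    def __init__(self, interactions: Iterable[Interaction] = (),
                 species_label: str = "") -> None:
        self.species_label = species_label
        self._edges: dict[tuple[str, str, str], Interaction] = {}
        for ia in interactions:
            self.add(ia)

    def add(self, ia: Interaction) -> None:
        existing = self._edges.get(ia.key)
        if existing is None:
            self._edges[ia.key] = Interaction(
                ia.regulator, ia.target, ia.regulator_type,
                set(ia.sources), ia.evidence)
        else:
            existing.sources |= ia.sources
            if not existing.evidence:
                existing.evidence = ia.evidence

    @property
    def interactions(self) -> list[Interaction]:
        return list(self._edges.values())

    @property
    def regulators(self) -> set[str]:
        return {r for (r, _, _) in self._edges}

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for r, t, _ in self._edges:
            out.add(r)
            out.add(t)
        return out

    def targets_of(self, regulator: str) -> set[str]:
        return {t for (r, t, _) in self._edges if r == regulator}

    def adjacency(self) -> dict[str, set[str]]:
        """Regulator -> set of targets, for every regulator in the network."""
        adj: dict[str, set[str]] = {}
        for r, t, _ in self._edges:
            adj.setdefault(r, set()).add(t)
        return adj

    def __len__(self) -> int:
        return len(self._edges)

    def __contains__(self, key: tuple[str, str, str]) -> bool:
        return key in self._edges

    def edge_keys(self) -> set[tuple[str, str, str]]:
        return set(self._edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReferenceNetwork):
            return NotImplemented
        return self.edge_keys() == other.edge_keys()


@dataclass
class GeneSetCollection:
    """Named functional categories, each a non-empty set of gene ids."""

    category_type: str = "custom"
    sets: dict[str, tuple[str, set[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category_type not in CATEGORY_TYPES:
            raise ValueError(
                f"category_type must be one of {CATEGORY_TYPES}, "
                f"got {self.category_type!r}")

    def members(self) -> dict[str, set[str]]:
        return {cid: genes for cid, (_, genes) in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)


def _clean_lines(path: str | Path) -> Iterable[tuple[int, str]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n").rstrip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def load_interactions(path: str | Path,
                      regulator_type_default: str = "TF",
                      species_label: str = "") -> ReferenceNetwork:
    """Read an interaction flat file into a deduplicated network.

    Lines with fewer than two fields are counted, skipped and warned about;
    an unrecognised type token is fatal because it signals data corruption
    rather than a sloppy row.
    """
    if regulator_type_default not in REGULATOR_TYPES:
        raise ValueError(f"bad regulator_type_default {regulator_type_default!r}")
    net = ReferenceNetwork(species_label=species_label)
    n_lines = n_malformed = 0
    for lineno, line in _clean_lines(path):
        n_lines += 1
        fields = line.split("\t")
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            n_malformed += 1
            logger.warning("%s:%d: malformed line skipped", path, lineno)
            continue
        rtype = fields[2].strip() if len(fields) > 2 and fields[2].strip() \
            else regulator_type_default
        if rtype not in REGULATOR_TYPES:
            raise ValueError(
                f"{path}:{lineno}: unknown regulator type {rtype!r}")
        sources = set()
        if len(fields) > 3 and fields[3].strip():
            sources = {s.strip() for s in fields[3].split(",") if s.strip()}
        evidence = fields[4].strip() if len(fields) > 4 else ""
        net.add(Interaction(fields[0].strip(), fields[1].strip(), rtype,
                            sources, evidence))
    n_dups = n_lines - n_malformed - len(net)
    logger.info("%s: %d lines, %d interactions, %d duplicates collapsed, "
                "%d malformed skipped", path, n_lines, len(net), n_dups,
                n_malformed)
    return net


def write_interactions(net: ReferenceNetwork, path: str | Path) -> None:
    """Write a network in the interaction flat-file dialect (round-trips)."""
    rows = sorted(net.interactions, key=lambda ia: ia.key)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#regulator\ttarget\ttype\tsources\tevidence\n")
        for ia in rows:
            fh.write(f"{ia.regulator}\t{ia.target}\t{ia.regulator_type}\t"
                     f"{','.join(sorted(ia.sources))}\t{ia.evidence}\n")


def merge_networks(nets: list[ReferenceNetwork]) -> ReferenceNetwork:
    """Union of several networks; duplicate edges union their sources."""
    labels = {n.species_label for n in nets if n.species_label}
    if len(labels) > 1:
        raise ValueError(f"species mismatch in merge: {sorted(labels)}")
    merged = ReferenceNetwork(species_label=labels.pop() if labels else "")
    for net in nets:
        for ia in net.interactions:
            merged.add(ia)
    return merged


def load_gene_sets(path: str | Path,
                   category_type: str = "custom") -> GeneSetCollection:
    """Read a GMT file (name, description, members...) into a collection.

    Lines with no members are skipped with a warning; duplicate members on
    one line collapse by set semantics.
    """
    coll = GeneSetCollection(category_type=category_type)
    for lineno, line in _clean_lines(path):
        fields = [f.strip() for f in line.split("\t")]
        name, desc = fields[0], fields[1] if len(fields) > 1 else ""
        members = {f for f in fields[2:] if f}
        if not members:
            logger.warning("%s:%d: gene set %r has no members, skipped",
                           path, lineno, name)
            continue
        if name in coll.sets:
            logger.warning("%s:%d: duplicate gene-set id %r overwritten",
                           path, lineno, name)
        coll.sets[name] = (desc, members)
    return coll


def load_alias_map(path: str | Path) -> dict[str, str]:
    """Two-column alias->canonical identifier mapping (tab-separated)."""
    mapping: dict[str, str] = {}
    for _, line in _clean_lines(path):
        fields = line.split("\t")
        if len(fields) >= 2 and fields[0].strip() and fields[1].strip():
            mapping[fields[0].strip()] = fields[1].strip()
    return mapping


def degree_rank_table(net: ReferenceNetwork) -> pd.DataFrame:
    """Out-degree of every regulator, ranked.

    Sorted by out-degree descending with ties broken by identifier; rank is
    1-based.  The degree-rank curve of a curated regulatory network is
    approximately a power law on log-log axes (exponent near -2), the
    hallmark of scale-free organisation.
    """
    counts: dict[str, int] = {}
    for r, _, _ in net.edge_keys():
        counts[r] = counts.get(r, 0) + 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        {"node": [r for r, _ in rows],
         "out_degree": [d for _, d in rows],
         "rank": range(1, len(rows) + 1)})


def apply_aliases(ids: Mapping[str, str] | None, gene: str) -> str:
    return ids.get(gene, gene) if ids else gene
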