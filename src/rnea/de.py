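"""Differential-expression input parsing and up/down/unchanged classification.

The pipeline expects a genome-wide table of per-gene log2 fold-changes and
p-values, as emitted by the common DE callers.  A gene is called
differentially expressed (DE) when both |log2FC| >= fc_threshold and
p <= p_threshold hold; the inequalities are inclusive, so boundary values
count as DE.  The set of measured genes doubles as the default finite
universe for the enrichment tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

logger = logging.getLogger(__name__)

UP, DOWN, UNCHANGED = "up", "down", "unchanged"


@dataclass
class DEProfile:
    """Per-gene DE measurements plus the threshold-derived status partition."""

    records: dict[str, tuple[float, float]] = field(default_factory=dict)
    status: dict[str, str] = field(default_factory=dict)
    fc_threshold: float | None = None
    p_threshold: float | None = None

    @property
    def universe(self) -> set[str]:
        return set(self.records)

    @property
    def up_genes(self) -> set[str]:
        return {g for g, s in self.status.items() if s == UP}

    @property
    def down_genes(self) -> set[str]:
        return {g for g, s in self.status.items() if s == DOWN}

    @property
    def de_genes(self) -> set[str]:
        return self.up_genes | self.down_genes

    def partition(self, name: str) -> set[str]:
        """DE genes of one partition: 'all', 'up' or 'down'."""
        if name == "all":
            return self.de_genes
        if name == UP:
            return self.up_genes
        if name == DOWN:
            return self.down_genes
        raise ValueError(f"unknown partition {name!r}")

    def status_of(self, gene: str) -> str:
        """Status of a gene; genes absent from the table are 'unmeasured'."""
        return self.status.get(gene, "unmeasured")


def parse_de_table(path: str | Path,
                   column_map: Mapping[str, str] | None = None,
                   alias_map: Mapping[str, str] | None = None,
                   sep: str | None = None,
                   fc_scale: float = 1.0) -> DEProfile:
    """Read a DE table into a profile with statuses unset.

    ``column_map`` names the gene / log2fc / pvalue columns (defaults
    ``gene``, ``log2fc``, ``pvalue``).  The delimiter is inferred from the
    extension (.csv -> comma, otherwise tab) unless ``sep`` is given.
    Duplicate gene rows collapse to the row with the smallest p-value
    (ties: largest |log2fc|, then first occurrence).  ``fc_scale``
    multiplies the fold-change column, for tables not already on the log2
    scale.  Rows with unparseable numerics are skipped with a warning.
    """
    cmap = {"gene": "gene", "log2fc": "log2fc", "pvalue": "pvalue"}
    if column_map:
        cmap.update(column_map)
    if sep is None:
        sep = "," if str(path).lower().endswith(".csv") else "\t"
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, comment="#",
                         skipinitialspace=True)
    except OSError as exc:
        raise RuntimeError(f"cannot read DE table {path}: {exc}") from exc
    df.columns = [c.strip() for c in df.columns]
    missing = [cmap[k] for k in ("gene", "log2fc", "pvalue")
               if cmap[k] not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; "
                         f"found {list(df.columns)}")

    records: dict[str, tuple[float, float]] = {}
    n_skipped = n_unmapped = 0
    for gene, fc_s, p_s in zip(df[cmap["gene"]], df[cmap["log2fc"]],
                               df[cmap["pvalue"]]):
        if not isinstance(gene, str) or not gene.strip():
            n_skipped += 1
            continue
        gene = gene.strip()
        try:
            fc = float(fc_s) * fc_scale
            p = float(p_s)
        except (TypeError, ValueError):
            n_skipped += 1
            continue
        if math.isnan(fc) or math.isnan(p) or not (0.0 <= p <= 1.0):
            n_skipped += 1
            continue
        if alias_map is not None:
            canonical = alias_map.get(gene)
            if canonical is None:
                n_unmapped += 1
            else:
                gene = canonical
        prev = records.get(gene)
        # keep min p-value; ties by larger |log2fc|, then first occurrence
        if prev is None or (p, -abs(fc)) < (prev[1], -abs(prev[0])):
            records[gene] = (fc, p)
    if n_skipped:
        logger.warning("%s: %d rows with unparseable values skipped",
                       path, n_skipped)
    if alias_map is not None and n_unmapped:
        logger.info("%s: %d identifiers had no alias mapping", path, n_unmapped)
    if not records:
        raise ValueError(f"{path}: no parseable DE rows")
    return DEProfile(records=records)


def classify(profile: DEProfile, fc_threshold: float = 1.0,
             p_threshold: float = 0.05) -> DEProfile:
    """Assign up/down/unchanged statuses under inclusive thresholds.

    up:   log2fc >= fc_threshold  and p <= p_threshold
    down: log2fc <= -fc_threshold and p <= p_threshold
    otherwise unchanged.  Returns a new profile; the input is unmodified.
    """
    if fc_threshold <= 0:
        raise ValueError("fc_threshold must be positive")
    if not (0 < p_threshold <= 1):
        raise ValueError("p_threshold must be in (0, 1]")
    if not profile.records:
        raise ValueError("cannot classify an empty profile")
    status = {}
    for gene, (fc, p) in profile.records.items():
        if p <= p_threshold and fc >= fc_threshold:
            status[gene] = UP
        elif p <= p_threshold and fc <= -fc_threshold:
            status[gene] = DOWN
        else:
            status[gene] = UNCHANGED
    return DEProfile(records=dict(profile.records), status=status,
                     fc_threshold=fc_threshold, p_threshold=p_threshold)
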