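"""Two-level regulator profiles and hypergeometric over-representation.

For every transcriptional regulator a *two-level profile* is built: its
direct targets (first level) plus, for each direct target that is itself a
regulator, that target's own targets (second level).  Expansion stops at
depth two — most curated regulatory interactions lead directly from a
regulator to a leaf gene, and deeper parsing would mostly chase cycles.

Each profile set, each miRNA first-level target set, and each functional
category is then tested for over-representation of deregulated genes with
the hypergeometric upper tail, separately for three partitions of the DE
list: all deregulated genes, strictly up-regulated, strictly down-regulated.
P-values are Benjamini-Hochberg adjusted within one (category type x
partition) family and the table is ranked by adjusted p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .de import DEProfile
from .network import GeneSetCollection, ReferenceNetwork

logger = logging.getLogger(__name__)

PARTITIONS = ("all", "up", "down")

#: universe choices for the finite population N of the hypergeometric test
UNIVERSE_MEASURED = "measured"      # genes present in the DE table (default)
UNIVERSE_ANNOTATION = "annotation"  # measured genes + all category members


@dataclass
class RegulatorProfile:
    """A regulator's two-level target set.

    ``second_level`` holds (intermediate, daughter) pairs where the
    intermediate is a first-level target that is itself a regulator.  The
    parent regulator never appears in its own profile set: cycles are
    truncated at the parent.
    """

    regulator: str
    first_level: set[str] = field(default_factory=set)
    second_level: set[tuple[str, str]] = field(default_factory=set)

    @property
    def profile_set(self) -> set[str]:
        daughters = {d for _, d in self.second_level}
        return (self.first_level | daughters) - {self.regulator}


def build_profiles(net: ReferenceNetwork) -> dict[str, RegulatorProfile]:
    """One two-level profile per regulator in the network."""
    adj = net.adjacency()
    profiles: dict[str, RegulatorProfile] = {}
    for reg, first in adj.items():
        second = {(t, d)
                  for t in first if t in adj
                  for d in adj[t] if d != reg}
        profiles[reg] = RegulatorProfile(reg, set(first), second)
    return profiles


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N genes in the universe, K of them in the category, n deregulated:
    the probability of observing at least k category members among the
    deregulated genes by chance alone.
    """
    if not (N >= 1 and 0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"invalid hypergeometric counts k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    p = float(hypergeom.sf(k - 1, N, K, n))
    # extreme tails underflow double precision; keep p strictly positive
    return max(p, 5e-324)


def bh_adjust(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    if not pvalues:
        return []
    for p in pvalues:
        if not (0 < p <= 1):
            raise ValueError(f"p-value {p} outside (0, 1]")
    return list(multipletests(pvalues, method="fdr_bh")[1])


@dataclass
class EnrichmentResult:
    """One category x partition over-representation test."""

    category_id: str
    category_type: str
    partition: str
    k: int          # DE genes of the partition inside the category
    K: int          # category size within the universe
    n: int          # DE genes of the partition within the universe
    N: int          # universe size
    p: float
    p_adj: float = 1.0
    rank: int = 0
    de_members: tuple[str, ...] = ()


def enrich(categories: dict[str, set[str]],
           profile: DEProfile,
           partition: str = "all",
           category_type: str = "custom",
           universe_policy: str = UNIVERSE_MEASURED) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of one partition's DE genes.

    Categories reduced to zero members after intersection with the universe
    are skipped (logged), keeping the BH family meaningful.  Results are
    sorted by adjusted p, ties by nominal p then category id, and ranked.
    """
    if partition not in PARTITIONS:
        raise ValueError(f"unknown partition {partition!r}")
    universe = profile.universe
    if universe_policy == UNIVERSE_ANNOTATION:
        universe = universe | set().union(*categories.values()) \
            if categories else universe
    elif universe_policy != UNIVERSE_MEASURED:
        raise ValueError(f"unknown universe policy {universe_policy!r}")
    if not universe:
        raise ValueError("empty universe: no measured genes")
    N = len(universe)
    de = profile.partition(partition) & universe
    n = len(de)

    results: list[EnrichmentResult] = []
    n_skipped = 0
    for cid, members in categories.items():
        members_u = members & universe
        K = len(members_u)
        if K == 0:
            n_skipped += 1
            continue
        hits = members_u & de
        k = len(hits)
        p = hypergeom_pvalue(k, K, n, N)
        results.append(EnrichmentResult(
            category_id=cid, category_type=category_type,
            partition=partition, k=k, K=K, n=n, N=N, p=p,
            de_members=tuple(sorted(hits))))
    if n_skipped:
        logger.info("%s/%s: %d categories outside the universe skipped",
                    category_type, partition, n_skipped)
    adjusted = bh_adjust([r.p for r in results])
    for r, pa in zip(results, adjusted):
        r.p_adj = pa
    results.sort(key=lambda r: (r.p_adj, r.p, r.category_id))
    for i, r in enumerate(results, start=1):
        r.rank = i
    return results


def run_all(net: ReferenceNetwork | None,
            mirna_net: ReferenceNetwork | None,
            gene_sets: list[GeneSetCollection],
            profile: DEProfile,
            universe_policy: str = UNIVERSE_MEASURED,
            first_level_only: bool = False
            ) -> dict[tuple[str, str], list[EnrichmentResult]]:
    """All enrichment tables: every supplied category type x all/up/down.

    TF categories are the two-level profile sets of the regulatory network
    (``first_level_only`` restricts them to direct targets); miRNA
    categories are the first-level target sets of the miRNA network;
    functional categories come from the gene-set collections.
    """
    families: list[tuple[str, dict[str, set[str]]]] = []
    if net is not None and len(net):
        profs = build_profiles(net)
        if first_level_only:
            cats = {r: set(p.first_level) - {r} for r, p in profs.items()}
        else:
            cats = {r: p.profile_set for r, p in profs.items()}
        families.append(("TF", {r: s for r, s in cats.items() if s}))
    if mirna_net is not None and len(mirna_net):
        families.append(("miRNA", mirna_net.adjacency()))
    for coll in gene_sets:
        families.append((coll.category_type, coll.members()))

    tables: dict[tuple[str, str], list[EnrichmentResult]] = {}
    for ctype, cats in families:
        for part in PARTITIONS:
            tables[(ctype, part)] = enrich(
                cats, profile, partition=part, category_type=ctype,
                universe_policy=universe_policy)
    return tables


def significant_categories(results: list[EnrichmentResult],
                           alpha: float = 0.05,
                           use_nominal: bool = False) -> set[str]:
    """Category ids passing the significance cutoff (adjusted by default)."""
    if use_nominal:
        return {r.category_id for r in results if r.p <= alpha}
    return {r.category_id for r in results if r.p_adj <= alpha}
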