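"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's own code paths: the
hypergeometric tail is recomputed from log-factorials, enrichment counts
by naive set intersection, and subnetwork extraction by flat enumeration
over edge pairs.
"""

from __future__ import annotations

import math
import random

import pytest

from rnea.network import Interaction, ReferenceNetwork


# ---------------------------------------------------------------- oracles

def hypergeom_tail_oracle(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k) via log-factorials, independent of scipy."""
    if k == 0:
        return 1.0

    def lchoose(a: int, b: int) -> float:
        if b < 0 or b > a:
            return float("-inf")
        return math.lgamma(a + 1) - math.lgamma(b + 1) - math.lgamma(a - b + 1)

    denom = lchoose(N, n)
    total = 0.0
    for i in range(k, min(K, n) + 1):
        total += math.exp(lchoose(K, i) + lchoose(N - K, n - i) - denom)
    return min(total, 1.0)


def subnetwork_rule_oracle(net: ReferenceNetwork, de: set[str],
                           seeds: set[str]) -> set[tuple[str, str, str]]:
    """Expected regulatory edges with rule tags, by flat pair enumeration.

    Returns {(source, target, rule)}.  Rule 2: seed->t with t deregulated,
    plus t->d chains when the seed and a daughter are both deregulated and
    t is; rule 3: the same chain with t NOT deregulated and the seed
    deregulated.  R2 wins over R3 on a duplicated edge.
    """
    edges = {(r, t) for (r, t, _k) in net.edge_keys()}
    out: dict[tuple[str, str], str] = {}

    def put(src: str, tgt: str, rule: str) -> None:
        if out.get((src, tgt)) != "R2_target_de":
            out[(src, tgt)] = rule

    for (r, t) in edges:
        if r in seeds and t in de:
            put(r, t, "R2_target_de")
    for (r, t) in edges:
        if r not in seeds:
            continue
        for (t2, d) in edges:
            if t2 != t or d == r:
                continue
            if t in de and d in de:
                put(t, d, "R2_target_de")
            elif t not in de and r in de and d in de:
                put(r, t, "R3_hidden_intermediate")
                put(t, d, "R3_hidden_intermediate")
    return {(s, t, rule) for (s, t), rule in out.items()}


def enrichment_counts_oracle(members: set[str], de: set[str],
                             universe: set[str]) -> tuple[int, int, int, int]:
    """(k, K, n, N) by naive intersection."""
    return (len(members & universe & de & universe),
            len(members & universe),
            len(de & universe),
            len(universe))


def random_network(rng: random.Random, n_nodes: int = 20,
                   n_edges: int = 30) -> ReferenceNetwork:
    """Random directed network; roughly half the nodes act as regulators."""
    nodes = [f"n{i}" for i in range(n_nodes)]
    possible_regs = nodes[: max(2, n_nodes // 2)]
    net = ReferenceNetwork()
    for _ in range(n_edges):
        r = rng.choice(possible_regs)
        t = rng.choice(nodes)
        net.add(Interaction(r, t, "TF"))
    return net


# --------------------------------------------------------------- fixtures

@pytest.fixture
def chain_example_network() -> ReferenceNetwork:
    """The canonical two-level worked example: R->B, B->B2, R->C, C->C1."""
    net = ReferenceNetwork()
    for r, t in [("R", "B"), ("B", "B2"), ("R", "C"), ("C", "C1")]:
        net.add(Interaction(r, t, "TF"))
    return net


@pytest.fixture
def chain_example_de() -> set[str]:
    """R, B, B2 and C1 deregulated; the intermediate C is not."""
    return {"R", "B", "B2", "C1"}


def make_profile(de_up: set[str], de_down: set[str],
                 unchanged: set[str]):
    """Classified DE profile with the given partition, synthetic values."""
    from rnea.de import DEProfile, classify
    records = {}
    for g in de_up:
        records[g] = (2.0, 0.001)
    for g in de_down:
        records[g] = (-2.0, 0.001)
    for g in unchanged:
        records[g] = (0.1, 0.9)
    return classify(DEProfile(records=records), 1.0, 0.05)
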