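"""Synthetic scale-free regulatory networks and planted-signal DE profiles.

The generator builds a directed regulator->target network by preferential
attachment on regulator out-degree: each new edge picks its source
regulator with probability proportional to (current out-degree + a), where
the small initial attractiveness ``a`` (default 0.08) yields a degree-rank
curve whose log-log slope sits near -2 — the empirical exponent of curated
regulatory networks.  A fraction of edges point at other regulators,
creating the two-level parent/daughter paths the subnetwork rules exploit.

On top of a network, a DE profile is planted: chosen "active" regulators
and a tunable fraction of their two-level profile members are emitted as
deregulated against a low background rate, mimicking the footprint a master
regulator leaves on expression.  Everything is deterministic given the
spec's seed and round-trips through the package's own table readers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import build_profiles
from .network import Interaction, ReferenceNetwork

_REG_FMT = "TF{:04d}"
_LEAF_FMT = "G{:05d}"


@dataclass
class SyntheticSpec:
    """Parameters of one simulated study.

    Defaults emulate a mid-size curated network (a few thousand nodes,
    roughly three edges per node) with one strongly active regulator:
    90% of its profile deregulated against a 5% genome-wide background,
    two-fold-change effects, and balanced up/down direction.
    """

    n_regulators: int = 200
    n_leaf_genes: int = 2000
    n_edges: int | None = None            # default: 3 x (regulators + leaves)
    attachment_exponent_target: float = -2.0
    initial_attractiveness: float = 0.08  # calibrated for slope near -2
    regulator_fraction_as_targets: float = 0.15
    planted_regulators: list[str] = field(default_factory=list)
    n_planted: int = 1                    # used when planted_regulators empty
    min_planted_out_degree: int = 20      # a master regulator has a regulon
    p_target_de: float = 0.9
    background_de_rate: float = 0.05
    effect_size_log2fc: float = 2.0
    direction_bias: float = 0.5
    fc_threshold: float = 1.0             # DE conventions the profile obeys
    p_threshold: float = 0.05
    first_level_only: bool = False        # plant over direct targets only
    regulator_type: str = "TF"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("regulator_fraction_as_targets", "p_target_de",
                     "background_de_rate", "direction_bias"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_regulators < 1 or self.n_leaf_genes < 0:
            raise ValueError("need at least one regulator and >= 0 leaves")
        if self.effect_size_log2fc <= 0:
            raise ValueError("effect_size_log2fc must be positive")


def generate_network(spec: SyntheticSpec) -> ReferenceNetwork:
    """Preferential-attachment regulator->target network.

    Deterministic given ``spec.seed``; no duplicate edges.  Regulator ids
    are TF0000..., leaves G00000....
    """
    rng = np.random.default_rng(spec.seed)
    R = spec.n_regulators
    regs = [_REG_FMT.format(i) for i in range(R)]
    leaves = [_LEAF_FMT.format(i) for i in range(spec.n_leaf_genes)]
    n_edges = spec.n_edges
    if n_edges is None:
        n_edges = 3 * (R + spec.n_leaf_genes)
    net = ReferenceNetwork(species_label="synthetic")
    deg = np.zeros(R)
    a = spec.initial_attractiveness
    seen: set[tuple[str, str]] = set()
    attempts = 0
    while len(seen) < n_edges and attempts < 20 * n_edges:
        attempts += 1
        w = deg + a
        src = int(rng.choice(R, p=w / w.sum()))
        if R > 1 and leaves and \
                rng.random() < spec.regulator_fraction_as_targets:
            tgt = regs[int(rng.integers(R))]
            if tgt == regs[src]:
                continue
        elif leaves:
            tgt = leaves[int(rng.integers(len(leaves)))]
        elif R > 1:
            tgt = regs[int(rng.integers(R))]
            if tgt == regs[src]:
                continue
        else:
            raise ValueError("infeasible spec: single regulator, no leaves")
        if (regs[src], tgt) in seen:
            continue
        seen.add((regs[src], tgt))
        deg[src] += 1
        net.add(Interaction(regs[src], tgt, spec.regulator_type,
                            {"synthetic"}))
    return net


def _pick_planted(net: ReferenceNetwork, spec: SyntheticSpec,
                  rng: np.random.Generator) -> list[str]:
    if spec.planted_regulators:
        missing = set(spec.planted_regulators) - net.regulators
        if missing:
            raise ValueError(f"planted regulators absent from the network: "
                             f"{sorted(missing)}")
        return list(spec.planted_regulators)
    # an "active master regulator" needs a regulon worth the name: sample
    # uniformly among regulators with enough direct targets, falling back
    # to the largest regulators when the cutoff empties the pool
    adj = net.adjacency()
    eligible = sorted(r for r, ts in adj.items()
                      if len(ts) >= spec.min_planted_out_degree)
    if not eligible:
        eligible = sorted(adj, key=lambda r: (-len(adj[r]), r))
        eligible = eligible[:max(spec.n_planted, 1)]
    idx = rng.choice(len(eligible), size=min(spec.n_planted, len(eligible)),
                     replace=False)
    return [eligible[i] for i in sorted(int(i) for i in idx)]


def plant_signal(net: ReferenceNetwork,
                 spec: SyntheticSpec) -> tuple[pd.DataFrame, list[str]]:
    """Emit a DE table (gene, log2fc, pvalue) with planted active regulators.

    Planted regulators are deregulated at |log2fc| = effect size with
    p ~ U(0, 0.01); each member of their (two-level) profile is deregulated
    with probability ``p_target_de`` and every other gene with probability
    ``background_de_rate``.  Direction of planted effects is up with
    probability ``direction_bias``.  Non-DE genes draw log2fc from
    N(0, 0.1 x effect) truncated inside the fold-change threshold and
    p ~ U(0.1, 1), so they can never cross the DE thresholds.

    Returns the table plus the planted regulator ids.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    planted = _pick_planted(net, spec, rng)
    profiles = build_profiles(net)
    in_profile: set[str] = set()
    for reg in planted:
        prof = profiles[reg]
        if spec.first_level_only:
            in_profile |= prof.first_level - {reg}
        else:
            in_profile |= prof.profile_set
    in_profile -= set(planted)

    genes = sorted(net.genes)
    eff = spec.effect_size_log2fc
    rows = []
    for gene in genes:
        if gene in planted:
            de, p_up = True, spec.direction_bias
        elif gene in in_profile:
            de = rng.random() < spec.p_target_de
            p_up = spec.direction_bias
        else:
            de = rng.random() < spec.background_de_rate
            p_up = 0.5
        if de:
            sign = 1.0 if rng.random() < p_up else -1.0
            log2fc = sign * (eff + abs(rng.normal(0.0, 0.25 * eff)))
            pval = rng.uniform(0.0, 0.01)
        else:
            x = rng.normal(0.0, 0.1 * eff)
            limit = 0.999 * spec.fc_threshold
            log2fc = float(np.clip(x, -limit, limit))
            pval = rng.uniform(0.1, 1.0)
        rows.append((gene, round(float(log2fc), 6), float(pval)))
    table = pd.DataFrame(rows, columns=["gene", "log2fc", "pvalue"])
    return table, planted


def write_de_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a planted DE table in the dialect the parser consumes."""
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def simulate(spec: SyntheticSpec, out_dir: str | Path
             ) -> dict[str, object]:
    """Generate network + DE table files for one spec; returns a manifest."""
    from .network import write_interactions

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net = generate_network(spec)
    table, planted = plant_signal(net, spec)
    net_path = out / "interactions.tsv"
    de_path = out / "de_table.tsv"
    write_interactions(net, net_path)
    write_de_table(table, de_path)
    return {
        "interactions": str(net_path),
        "de_table": str(de_path),
        "n_interactions": len(net),
        "n_regulators": len(net.regulators),
        "n_genes": len(net.genes),
        "planted_regulators": planted,
        "seed": spec.seed,
    }


def spec_from_dict(d: dict) -> SyntheticSpec:
    """Build a spec from a plain dict (e.g. loaded from YAML)."""
    return SyntheticSpec(**d)


def with_seed(spec: SyntheticSpec, seed: int) -> SyntheticSpec:
    return replace(spec, seed=seed)
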