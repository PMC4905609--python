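"""Rule-based subnetwork extraction, functional/global modes, TSV I/O."""

import random

import pytest

from rnea.enrichment import run_all
from rnea.network import GeneSetCollection, Interaction, ReferenceNetwork
from rnea.subnetwork import (extract_functional, extract_global,
                             extract_regulatory, read_subnetwork,
                             write_subnetwork)

from conftest import make_profile, random_network, subnetwork_rule_oracle

R2, R3 = "R2_target_de", "R3_hidden_intermediate"


def de_profile_for(net, de_genes, extra_unchanged=()):
    universe = net.genes | set(extra_unchanged)
    return make_profile(set(de_genes), set(), universe - set(de_genes))


class TestWorkedChainExample:
    """R regulates B and C; B and C regulate B2 and C1; C is not DE."""

    def test_exact_edges_rules_and_hidden_flag(self, chain_example_network,
                                               chain_example_de):
        profile = de_profile_for(chain_example_network, chain_example_de)
        sub = extract_regulatory(chain_example_network, None, profile)
        assert {(s, t, r) for (s, t, _k), r in sub.edges.items()} == {
            ("R", "B", R2), ("B", "B2", R2),
            ("R", "C", R3), ("C", "C1", R3)}
        assert sub.nodes["C"].status == "unchanged"
        assert sub.hidden_intermediates == {"C"}
        assert sub.nodes["R"].node_type == "TF"
        assert sub.nodes["B2"].node_type == "gene"

    def test_no_de_genes_no_seeds_empty(self, chain_example_network):
        profile = de_profile_for(chain_example_network, set())
        sub = extract_regulatory(chain_example_network, None, profile)
        assert len(sub) == 0 and not sub.nodes


class TestRuleOracleEquivalence:
    def test_matches_exhaustive_enumeration_on_random_networks(self):
        rng = random.Random(99)
        for trial in range(40):
            net = random_network(rng, rng.randint(6, 40), rng.randint(5, 60))
            genes = sorted(net.genes)
            de = {g for g in genes if rng.random() < 0.4}
            profile = de_profile_for(net, de)
            seeds = {r for r in net.regulators if r in de}
            sub = extract_regulatory(net, None, profile, seed_mode="de")
            got = {(s, t, r) for (s, t, _k), r in sub.edges.items()}
            want = subnetwork_rule_oracle(net, de, seeds)
            assert got == want, f"trial {trial}"

    def test_monotone_in_de_set(self):
        rng = random.Random(5)
        for _ in range(15):
            net = random_network(rng, 20, 35)
            genes = sorted(net.genes)
            de_small = {g for g in genes if rng.random() < 0.25}
            extra = {g for g in genes if rng.random() < 0.25}
            small = extract_regulatory(
                net, None, de_profile_for(net, de_small))
            large = extract_regulatory(
                net, None, de_profile_for(net, de_small | extra))
            assert set(small.edges) <= set(large.edges)

    def test_hidden_intermediates_bridge_de_endpoints(self):
        rng = random.Random(17)
        for _ in range(15):
            net = random_network(rng, 25, 50)
            de = {g for g in sorted(net.genes) if rng.random() < 0.35}
            profile = de_profile_for(net, de)
            sub = extract_regulatory(net, None, profile)
            for h in sub.hidden_intermediates:
                incoming = [(s, t) for (s, t, _k) in sub.edges
                            if t == h and s in de]
                outgoing = [(s, t) for (s, t, _k) in sub.edges
                            if s == h and t in de]
                assert incoming and outgoing, h

    def test_subnetwork_subset_of_reference(self):
        rng = random.Random(23)
        net = random_network(rng, 30, 70)
        de = {g for g in sorted(net.genes) if rng.random() < 0.5}
        sub = extract_regulatory(net, None, de_profile_for(net, de))
        ref_edges = {(r, t) for (r, t, _k) in net.edge_keys()}
        assert {(s, t) for (s, t, _k) in sub.edges} <= ref_edges


class TestSeedModes:
    def setup_method(self):
        self.net = ReferenceNetwork(
            [Interaction("T1", f"g{i}") for i in range(6)]
            + [Interaction("T2", "g9")])
        # T1's whole target set is DE but T1 itself is not measured as DE
        self.profile = de_profile_for(
            self.net, {f"g{i}" for i in range(6)})
        self.tables = run_all(self.net, None, [], self.profile)

    def test_de_seeding_excludes_unchanged_regulator(self):
        sub = extract_regulatory(self.net, None, self.profile,
                                 seed_mode="de")
        assert len(sub) == 0

    def test_enriched_seeding_recovers_it(self):
        sub = extract_regulatory(self.net, None, self.profile,
                                 enrichments=self.tables,
                                 seed_mode="enriched", alpha=0.05)
        assert {(s, t) for (s, t, _k) in sub.edges} == {
            ("T1", f"g{i}") for i in range(6)}
        # non-DE seed cannot spawn rule-3 chains
        assert all(r == R2 for r in sub.edges.values())

    def test_enriched_without_tables_fatal(self):
        with pytest.raises(ValueError, match="requires enrichment"):
            extract_regulatory(self.net, None, self.profile,
                               seed_mode="enriched")


class TestMiRNASeeding:
    def test_enriched_mirna_contributes_edges_to_de_targets(self):
        net = ReferenceNetwork([Interaction("T1", "x")])
        mirna = ReferenceNetwork(
            [Interaction("mir-9", f"g{i}", "miRNA") for i in range(10)]
            + [Interaction("mir-9", "u0", "miRNA")])
        de = {f"g{i}" for i in range(10)}
        profile = make_profile(de, set(), {"x", "u0", "T1"})
        tables = run_all(net, mirna, [], profile)
        sub = extract_regulatory(net, mirna, profile, enrichments=tables)
        mirna_edges = {(s, t) for (s, t, k) in sub.edges
                       if k == "miRNA_target"}
        assert mirna_edges == {("mir-9", f"g{i}") for i in range(10)}
        assert sub.nodes["mir-9"].node_type == "miRNA"
        assert sub.nodes["mir-9"].status == "unmeasured"


class TestFunctionalAndGlobal:
    def setup_method(self):
        genes = [f"g{i}" for i in range(30)]
        self.de = set(genes[:6])
        self.coll = GeneSetCollection("GO", {
            "HIT": ("matches DE list", set(genes[:6]) | {"g7", "g8"}),
            "MISS": ("background", set(genes[10:20]))})
        self.profile = make_profile(self.de, set(), set(genes) - self.de)
        self.tables = run_all(None, None, [self.coll], self.profile)

    def test_enriched_category_links_de_members_only(self):
        sub = extract_functional([self.coll], self.tables, self.profile)
        edges = {(s, t) for (s, t, _k) in sub.edges}
        assert edges == {("HIT", g) for g in self.de}
        assert "MISS" not in sub.nodes
        assert sub.nodes["HIT"].node_type == "GO"

    def test_no_enriched_categories_empty(self):
        profile = make_profile(set(), set(), {f"g{i}" for i in range(30)})
        tables = run_all(None, None, [self.coll], profile)
        sub = extract_functional([self.coll], tables, profile)
        assert len(sub) == 0

    def test_global_union(self, chain_example_network, chain_example_de):
        reg_profile = de_profile_for(chain_example_network, chain_example_de)
        reg = extract_regulatory(chain_example_network, None, reg_profile)
        func = extract_functional([self.coll], self.tables, self.profile)
        glob = extract_global(reg, func)
        assert len(glob) == len(reg) + len(func)  # disjoint here
        assert set(glob.nodes) == set(reg.nodes) | set(func.nodes)
        kinds = {k for (_s, _t, k) in glob.edges}
        assert kinds == {"TF_target", "category_member"}

    def test_global_with_empty_is_identity(self, chain_example_network,
                                           chain_example_de):
        from rnea.subnetwork import Subnetwork
        reg = extract_regulatory(
            chain_example_network, None,
            de_profile_for(chain_example_network, chain_example_de))
        glob = extract_global(reg, Subnetwork())
        assert glob.edge_set() == reg.edge_set()
        assert glob.nodes == reg.nodes


class TestSerialization:
    def test_chain_example_written_deterministically(
            self, tmp_path, chain_example_network, chain_example_de):
        profile = de_profile_for(chain_example_network, chain_example_de)
        sub = extract_regulatory(chain_example_network, None, profile)
        p1, n1 = write_subnetwork(sub, tmp_path / "a.tsv")
        p2, n2 = write_subnetwork(sub, tmp_path / "b.tsv")
        lines = p1.read_text().splitlines()
        assert len(lines) == 5  # header + 4 edges
        assert lines[0].split("\t") == [
            "source", "interaction", "target", "rule", "source_status",
            "target_status", "source_type", "target_type"]
        assert p1.read_text() == p2.read_text()
        assert n1.read_text() == n2.read_text()

    def test_empty_subnetwork_header_only(self, tmp_path):
        from rnea.subnetwork import Subnetwork
        p, n = write_subnetwork(Subnetwork(), tmp_path / "e.tsv")
        assert p.read_text().count("\n") == 1
        assert n.read_text().count("\n") == 1

    def test_round_trip(self, tmp_path):
        rng = random.Random(31)
        net = random_network(rng, 25, 60)
        de = {g for g in sorted(net.genes) if rng.random() < 0.4}
        sub = extract_regulatory(net, None, de_profile_for(net, de))
        p, n = write_subnetwork(sub, tmp_path / "rt.tsv")
        back = read_subnetwork(p, n)
        assert back.edge_set() == sub.edge_set()
        assert back.nodes == sub.nodes
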