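"""Triple construction, mechanism filter, network export."""

import itertools

import pandas as pd
import pytest

from flycerna.cerna import (
    MECHANISM_PATTERNS,
    export_network,
    find_triples,
    mechanism_filter,
)


def site_row(mirna, target, target_class, start=10):
    return {
        "mirna": mirna, "target": target, "target_class": target_class,
        "start": start, "end": start + 7, "seed_class": "8mer",
        "score": 145.0, "energy": -25.0,
    }


def de_frame(features_dirs):
    return pd.DataFrame(
        [{"feature": f, "log2fc": 2.0 if d == "up" else -2.0,
          "p_raw": 0.01, "p_adj": 0.02, "direction": d}
         for f, d in features_dirs]
    )


@pytest.fixture
def de_tables():
    return {
        "circrna": de_frame([("circ1", "down"), ("circ2", "up")]),
        "lncrna": de_frame([("lnc1", "up")]),
        "mirna": de_frame([("mir1", "up"), ("mir2", "down"), ("mir3", "ns")]),
        "mrna": de_frame([("gA", "down"), ("gB", "up"), ("gC", "ns")]),
    }


class TestFindTriples:
    def test_shared_mirna_joins_sponge_and_mrna(self, de_tables):
        sites = pd.DataFrame([
            site_row("mir1", "circ1", "circRNA"),
            site_row("mir1", "gA", "mRNA_3UTR"),
        ])
        out = find_triples(sites, de_tables)
        assert len(out) == 1
        r = out.iloc[0]
        assert (r["sponge"], r["mirna"], r["mrna"]) == ("circ1", "mir1", "gA")
        assert (r["dir_sponge"], r["dir_mirna"], r["dir_mrna"]) == (
            "down", "up", "down"
        )
        assert r["mechanism_pass"]

    def test_one_sided_evidence_gives_no_triple(self, de_tables):
        sites = pd.DataFrame([site_row("mir1", "circ1", "circRNA")])
        assert find_triples(sites, de_tables).empty

    def test_ns_members_excluded(self, de_tables):
        sites = pd.DataFrame([
            site_row("mir3", "circ1", "circRNA"),   # miRNA is ns
            site_row("mir3", "gA", "mRNA_3UTR"),
            site_row("mir1", "circ1", "circRNA"),
            site_row("mir1", "gC", "mRNA_3UTR"),    # mRNA is ns
        ])
        assert find_triples(sites, de_tables).empty

    def test_missing_assay_raises_with_name(self, de_tables):
        del de_tables["lncrna"]
        sites = pd.DataFrame([site_row("mir1", "circ1", "circRNA")])
        with pytest.raises(KeyError, match="lncrna"):
            find_triples(sites, de_tables)

    def test_site_counts_carried_per_side(self, de_tables):
        sites = pd.DataFrame([
            site_row("mir1", "circ1", "circRNA", 10),
            site_row("mir1", "circ1", "circRNA", 50),
            site_row("mir1", "gA", "mRNA_3UTR", 20),
        ])
        r = find_triples(sites, de_tables).iloc[0]
        assert (r["n_sites_sponge"], r["n_sites_mrna"]) == (2, 1)

    def test_equals_brute_force_join_oracle(self, de_tables, rng):
        sponges = [("circ1", "circRNA"), ("circ2", "circRNA"), ("lnc1", "lncRNA")]
        mirnas = ["mir1", "mir2", "mir3"]
        mrnas = ["gA", "gB", "gC"]
        rows = []
        for m in mirnas:
            for s, cls in sponges:
                if rng.random() < 0.5:
                    rows.append(site_row(m, s, cls))
            for g in mrnas:
                if rng.random() < 0.5:
                    rows.append(site_row(m, g, "mRNA_3UTR"))
        sites = pd.DataFrame(rows)
        got = {
            (r["sponge"], r["mirna"], r["mrna"])
            for _, r in find_triples(sites, de_tables).iterrows()
        }
        # Independent brute-force enumeration over all combinations.
        def is_de(table, f):
            sub = table.loc[table["feature"] == f, "direction"]
            return len(sub) and sub.item() != "ns"

        has = {(r["mirna"], r["target"]) for r in rows}
        expected = set()
        for (s, cls), m, g in itertools.product(sponges, mirnas, mrnas):
            tab = de_tables["circrna" if cls == "circRNA" else "lncrna"]
            if (
                (m, s) in has and (m, g) in has
                and is_de(tab, s) and is_de(de_tables["mirna"], m)
                and is_de(de_tables["mrna"], g)
            ):
                expected.add((s, m, g))
        assert got == expected

    def test_row_order_permutation_invariant(self, de_tables, rng):
        rows = [
            site_row("mir1", "circ1", "circRNA"),
            site_row("mir1", "gA", "mRNA_3UTR"),
            site_row("mir2", "lnc1", "lncRNA"),
            site_row("mir2", "gB", "mRNA_3UTR"),
        ]
        sites = pd.DataFrame(rows)
        shuffled = sites.sample(frac=1, random_state=4).reset_index(drop=True)
        a = find_triples(sites, de_tables)
        b = find_triples(shuffled, de_tables)
        pd.testing.assert_frame_equal(a, b)


class TestMechanismFilter:
    def triple(self, ds, dmi, dmr):
        return pd.DataFrame([{
            "sponge": "s", "sponge_class": "circRNA", "mirna": "m",
            "mrna": "g", "dir_sponge": ds, "dir_mirna": dmi, "dir_mrna": dmr,
            "n_sites_sponge": 1, "n_sites_mrna": 1, "mechanism_pass": False,
        }])

    def test_exactly_two_of_eight_patterns_pass(self):
        passing = []
        for combo in itertools.product(("up", "down"), repeat=3):
            kept = mechanism_filter(self.triple(*combo))
            if len(kept):
                passing.append(combo)
        assert set(passing) == MECHANISM_PATTERNS
        assert len(passing) == 2

    def test_co_directional_mirna_rejected(self):
        assert mechanism_filter(self.triple("down", "down", "down")).empty

    def test_ns_member_rejected(self):
        assert mechanism_filter(self.triple("up", "ns", "up")).empty

    def test_subset_and_idempotent(self, de_tables):
        sites = pd.DataFrame([
            site_row("mir1", "circ1", "circRNA"),
            site_row("mir1", "gA", "mRNA_3UTR"),
            site_row("mir2", "circ2", "circRNA"),
            site_row("mir2", "gB", "mRNA_3UTR"),
        ])
        triples = find_triples(sites, de_tables)
        once = mechanism_filter(triples)
        keys = {"sponge", "mirna", "mrna"}
        assert set(map(tuple, once[list(keys)].values)) <= set(
            map(tuple, triples[list(keys)].values)
        )
        twice = mechanism_filter(once)
        pd.testing.assert_frame_equal(once, twice)


class TestExportNetwork:
    def test_single_triple_network(self):
        t = TestMechanismFilter().triple("up", "down", "up")
        edges, nodes = export_network(t)
        assert len(edges) == 2 and len(nodes) == 3
        assert set(edges["edge_type"]) == {"sponge-miRNA", "miRNA-mRNA"}

    def test_shared_edge_deduplicated(self):
        a = TestMechanismFilter().triple("up", "down", "up")
        b = a.copy()
        b["sponge"] = "s2"  # same miRNA-mRNA pair, different sponge
        edges, nodes = export_network(pd.concat([a, b], ignore_index=True))
        assert len(edges) == 3  # two sponge edges + one shared miRNA-mRNA
        assert len(nodes) == 4

    def test_node_counts_match_distinct_members(self, de_tables):
        sites = pd.DataFrame([
            site_row("mir1", "circ1", "circRNA"),
            site_row("mir1", "gA", "mRNA_3UTR"),
            site_row("mir2", "lnc1", "lncRNA"),
            site_row("mir2", "gB", "mRNA_3UTR"),
        ])
        triples = find_triples(sites, de_tables)
        _, nodes = export_network(triples)
        for col, cls in (("sponge", ("circRNA", "lncRNA")), ("mirna", ("miRNA",)),
                         ("mrna", ("mRNA",))):
            distinct = triples[col].nunique()
            assert (nodes["node_class"].isin(cls)).sum() == distinct

    def test_empty_input_gives_empty_tables(self):
        empty = TestMechanismFilter().triple("up", "down", "up").iloc[0:0]
        edges, nodes = export_network(empty)
        assert edges.empty and nodes.empty
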