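"""ceRNA triple construction and the sign-consistency mechanism filter.

A sponge (circRNA or lncRNA), a miRNA and an mRNA form a candidate triple
when the miRNA has at least one predicted binding site on both the sponge
and the mRNA 3'UTR and all three members are differentially expressed.
The ceRNA mechanism predicts sponge and mRNA to move together and the
miRNA to move opposite; of the 8 possible direction triplets only
(up, down, up) and (down, up, down) conform.
"""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd

__all__ = [
    "find_triples",
    "mechanism_filter",
    "export_network",
    "MECHANISM_PATTERNS",
]

logger = logging.getLogger(__name__)

SPONGE_CLASSES = ("circRNA", "lncRNA")
MECHANISM_PATTERNS = {("up", "down", "up"), ("down", "up", "down")}

TRIPLE_COLUMNS = [
    "sponge", "sponge_class", "mirna", "mrna",
    "dir_sponge", "dir_mirna", "dir_mrna",
    "n_sites_sponge", "n_sites_mrna", "mechanism_pass",
]

_ASSAY_OF_CLASS = {"circRNA": "circrna", "lncRNA": "lncrna", "mRNA_3UTR": "mrna"}


def _direction_map(de_tables: dict[str, pd.DataFrame], assay: str) -> dict[str, str]:
    if assay not in de_tables:
        raise KeyError(f"DE table for assay {assay!r} missing from de_tables")
    df = de_tables[assay]
    return dict(zip(df["feature"], df["direction"]))


def find_triples(
    sites: pd.DataFrame, de_tables: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Join sponge-side and mRNA-side site tables on the shared miRNA.

    ``sites`` is a binding-site table covering sponge classes and
    mRNA_3UTR targets; ``de_tables`` maps assay ('circrna', 'lncrna',
    'mirna', 'mrna') to DE tables with feature/direction columns. Only
    DE members (direction != ns) enter triples. One row per
    (sponge, miRNA, mRNA), sorted by (sponge, mirna, mrna), with per-side
    site counts and the mechanism flag pre-computed.
    """
    dirs = {
        assay: _direction_map(de_tables, assay)
        for assay in ("circrna", "lncrna", "mirna", "mrna")
    }

    def de_dir(assay: str, feature: str) -> str | None:
        d = dirs[assay].get(feature, "ns")
        return None if d == "ns" else d

    sponge_sites = sites[sites["target_class"].isin(SPONGE_CLASSES)]
    mrna_sites = sites[sites["target_class"] == "mRNA_3UTR"]

    sponge_counts = (
        sponge_sites.groupby(["mirna", "target", "target_class"]).size()
    )
    mrna_counts = mrna_sites.groupby(["mirna", "target"]).size()

    rows = []
    for (mirna, sponge, sponge_class), n_sp in sponge_counts.items():
        d_mir = de_dir("mirna", mirna)
        d_sp = de_dir(_ASSAY_OF_CLASS[sponge_class], sponge)
        if d_mir is None or d_sp is None:
            continue
        for (mirna2, mrna), n_mr in mrna_counts.items():
            if mirna2 != mirna:
                continue
            d_mr = de_dir("mrna", mrna)
            if d_mr is None:
                continue
            rows.append(
                {
                    "sponge": sponge,
                    "sponge_class": sponge_class,
                    "mirna": mirna,
                    "mrna": mrna,
                    "dir_sponge": d_sp,
                    "dir_mirna": d_mir,
                    "dir_mrna": d_mr,
                    "n_sites_sponge": int(n_sp),
                    "n_sites_mrna": int(n_mr),
                    "mechanism_pass": (d_sp, d_mir, d_mr) in MECHANISM_PATTERNS,
                }
            )
    df = pd.DataFrame(rows, columns=TRIPLE_COLUMNS)
    return df.sort_values(["sponge", "mirna", "mrna"], kind="stable").reset_index(
        drop=True
    )


def mechanism_filter(triples: pd.DataFrame) -> pd.DataFrame:
    """Keep triples conforming to the ceRNA mechanism.

    Accepts exactly the direction triplets (up, down, up) and
    (down, up, down); rows with any 'ns' member are rejected (logged).
    The returned table carries ``mechanism_pass`` set for every input row.
    """
    out = triples.copy()
    has_ns = (
        out[["dir_sponge", "dir_mirna", "dir_mrna"]].eq("ns").any(axis=1)
    )
    for _, row in out[has_ns].iterrows():
        logger.info(
            "triple %s/%s/%s rejected: non-significant member",
            row["sponge"], row["mirna"], row["mrna"],
        )
    out["mechanism_pass"] = [
        (s, mi, mr) in MECHANISM_PATTERNS and not ns
        for s, mi, mr, ns in zip(
            out["dir_sponge"], out["dir_mirna"], out["dir_mrna"], has_ns
        )
    ]
    return out[out["mechanism_pass"]].reset_index(drop=True)


def export_network(triples: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bipartite edge list (sponge-miRNA, miRNA-mRNA) and node table.

    Edges are deduplicated; nodes carry class and DE direction. Both
    tables use a stable lexicographic ordering.
    """
    g = nx.Graph()
    for _, r in triples.iterrows():
        g.add_node(r["sponge"], node_class=r["sponge_class"], direction=r["dir_sponge"])
        g.add_node(r["mirna"], node_class="miRNA", direction=r["dir_mirna"])
        g.add_node(r["mrna"], node_class="mRNA", direction=r["dir_mrna"])
        g.add_edge(r["sponge"], r["mirna"], edge_type="sponge-miRNA")
        g.add_edge(r["mirna"], r["mrna"], edge_type="miRNA-mRNA")
    edges = pd.DataFrame(
        sorted(
            (min(u, v), max(u, v), d["edge_type"]) for u, v, d in g.edges(data=True)
        ),
        columns=["node_a", "node_b", "edge_type"],
    )
    nodes = pd.DataFrame(
        sorted(
            (n, d["node_class"], d["direction"]) for n, d in g.nodes(data=True)
        ),
        columns=["node", "node_class", "direction"],
    )
    return edges, nodes
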