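"""GO term enrichment of network target genes.

One-sided (upper-tail) hypergeometric test per term with BH correction
across all tested terms; terms are tested exactly as mapped (no GO-DAG
ancestor propagation). The report mirrors the study's convention of
listing the first 30 terms by lowest p.
"""

from __future__ import annotations

import re

import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

__all__ = ["validate_gomap", "hypergeom_enrich", "top_terms"]

GO_ID_RE = re.compile(r"^GO:\d{7}$")
NAMESPACES = {"BP", "CC", "MF"}

RESULT_COLUMNS = [
    "go_id", "term", "namespace", "k", "n", "K", "N", "p_raw", "p_adj",
]


def validate_gomap(gomap: pd.DataFrame) -> pd.DataFrame:
    """Check a gene -> GO mapping (columns gene, go_id, term, namespace)."""
    bad = [g for g in gomap["go_id"].unique() if not GO_ID_RE.match(str(g))]
    if bad:
        raise ValueError(f"malformed GO ids: {bad[:5]}")
    bad_ns = set(gomap["namespace"].unique()) - NAMESPACES
    if bad_ns:
        raise ValueError(f"unknown namespaces: {sorted(bad_ns)}")
    if gomap.duplicated(["gene", "go_id"]).any():
        raise ValueError("duplicate (gene, GO id) pairs in mapping")
    return gomap


def hypergeom_enrich(
    query: set[str] | list[str],
    gomap: pd.DataFrame,
    background: set[str] | list[str] | None = None,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``query`` genes per GO term.

    ``background`` defaults to all genes in the mapping united with the
    query universe; unannotated background genes still count toward N.
    p = P(X >= k) for X ~ Hypergeometric(N, K, n). Terms with no query
    member are not reported. BH adjustment across all reported terms.
    """
    query = set(query)
    if not query:
        raise ValueError("query gene set is empty")
    validate_gomap(gomap)
    if background is None:
        background = set(gomap["gene"]) | query
    background = set(background)
    strays = sorted(query - background)
    if strays:
        raise ValueError(f"query genes absent from background: {strays}")

    annotated = gomap[gomap["gene"].isin(background)]
    N, n = len(background), len(query)
    rows = []
    for (go_id, term, ns), grp in annotated.groupby(["go_id", "term", "namespace"]):
        members = set(grp["gene"])
        k = len(members & query)
        if k == 0:
            continue
        K = len(members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((go_id, term, ns, k, n, K, N, p))
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS[:-1])
    df["p_adj"] = bh_adjust(df["p_raw"].values) if len(df) else []
    return df.sort_values(["p_raw", "go_id"], kind="stable").reset_index(drop=True)


def top_terms(
    results: pd.DataFrame, n_top: int = 30, by: str = "p_raw"
) -> pd.DataFrame:
    """First ``n_top`` terms by lowest p, ties broken by GO id."""
    return (
        results.sort_values([by, "go_id"], kind="stable")
        .head(n_top)
        .reset_index(drop=True)
    )
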