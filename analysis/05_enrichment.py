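#!/usr/bin/env python
"""GO enrichment of the ceRNA-network target genes.

Takes the mRNAs of the mechanism-passing triples as the query, the
simulated GO map as annotation, and reports the top terms by lowest
hypergeometric p (at most 30), BH-adjusted.
"""

from pathlib import Path

from flycerna.enrich import hypergeom_enrich, top_terms
from flycerna.io import read_tsv, write_tsv

STUDY = Path("results/study")
OUT = Path("results")


def main() -> None:
    triples = read_tsv(OUT / "triples.tsv")
    gomap = read_tsv(STUDY / "go_map.tsv")
    targets = sorted(set(triples["mrna"]))
    if not targets:
        print("no network targets; nothing to enrich")
        return
    res = top_terms(hypergeom_enrich(targets, gomap), n_top=30)
    write_tsv(res, OUT / "enrichment.tsv")
    print(f"query of {len(targets)} network mRNAs against "
          f"{gomap['go_id'].nunique()} terms; top hits:")
    for _, r in res.head(5).iterrows():
        print(f"  {r['go_id']} [{r['namespace']}] {r['term']}: "
              f"k={r['k']}/{r['K']}, p={r['p_raw']:.3g} (adj {r['p_adj']:.3g})")


if __name__ == "__main__":
    main()
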