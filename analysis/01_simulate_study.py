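#!/usr/bin/env python
"""Generate the synthetic two-age study (sequences, counts, Ct, truth).

Emulates the study design: day 7 vs day 42, RNA-seq (mRNA/lncRNA/circRNA)
with 2 biological replicates, miRNA-seq with 5, NB counts with planted
|log2fc| = 2 effects and 10 planted sponge/miRNA/mRNA triples. Writes
FASTA, count/design/Ct TSVs, a synthetic GO map and the ground truth to
results/study/.
"""

from pathlib import Path

from flycerna.io import write_fasta, write_ground_truth, write_tsv
from flycerna.pipeline import simulate_gomap
from flycerna.simdata import (
    SimulationConfig,
    simulate_counts,
    simulate_ct,
    simulate_sequences,
)

OUT = Path("results/study")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(seed=SEED)
    seqs, truth = simulate_sequences(cfg)
    counts = simulate_counts(truth, cfg)
    ct = simulate_ct(truth, cfg)
    gomap = simulate_gomap(truth, cfg)

    for assay, seq_map in seqs.items():
        write_fasta(OUT / f"{assay}.fasta", seq_map)
    write_tsv(cfg.design().reset_index(), OUT / "design.tsv")
    for assay, cm in counts.items():
        write_tsv(
            cm.counts.rename_axis("feature").reset_index(),
            OUT / f"counts_{assay}.tsv",
        )
    write_tsv(ct, OUT / "ct.tsv")
    write_tsv(gomap, OUT / "go_map.tsv")
    write_ground_truth(OUT / "ground_truth.json", truth)

    n_feat = sum(len(v) for v in seqs.values())
    print(f"simulated {n_feat} features, {len(truth.planted_triples)} planted "
          f"triples, {len(truth.planted_sites)} planted sites -> {OUT}")


if __name__ == "__main__":
    main()
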