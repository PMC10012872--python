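# flycerna

Age-related ceRNA (competing endogenous RNA) network inference for
two-condition RNA-seq designs, modelled on a day-7 vs day-42 adult
*Drosophila* ageing study.

circRNAs and lncRNAs can act as miRNA sponges: by carrying the same
binding sites as an mRNA 3'UTR they sequester the miRNA and de-repress
its targets. The ceRNA model therefore predicts, for a sponge/miRNA/mRNA
triple, that sponge and mRNA move **together** across conditions while
the miRNA moves **opposite**. `flycerna` implements the full inference
chain for this model:

1. **Differential expression** — exact conditional negative-binomial
   test per feature. Counts are NB(mu, alpha) with Var = mu + alpha·mu²;
   after median-of-ratios normalization the group-A sum given the total
   is BetaBinomial(total, n_A/alpha, n_B/alpha), and the two-sided p sums
   all partitions no more likely than the observed one. BH adjustment;
   screens: circRNA raw p < 0.05, miRNA |FC| >= 1.5 and raw p < 0.05.
2. **Binding sites** — canonical seed matching (8mer / 7mer-m8 /
   7mer-A1 / 6mer, no G:U in the seed), miRanda-style local hybrid
   alignment (match +5, wobble +2, mismatch −3, gaps −9/−4, seed
   positions doubled) and nearest-neighbor RNA:RNA duplex free energy;
   defaults score >= 140, dG <= −10 kcal/mol. circRNAs are scanned with
   wrap-around so back-splice-junction sites are found.
3. **ceRNA triples** — join sponge-side and 3'UTR-side sites on the
   shared miRNA, restrict to DE members, and keep the two
   mechanism-conforming direction patterns (up, down, up) and
   (down, up, down).
4. **GO enrichment** — upper-tail hypergeometric p per term,
   P(X >= k), X ~ Hypergeom(N, K, n), BH-corrected, top 30 by lowest p.
5. **qPCR concordance** — 2^−ddCt against rp49 with day 7 as
   calibrator, Welch t-test on ddCt, and "(+)" flags where qPCR agrees
   with the sequencing call in direction and significance.

A synthetic-data generator reproduces the study design (2 RNA-seq / 5
miRNA-seq replicates per condition, NB counts with planted |log2fc| = 2,
planted sign-consistent triples) with exported ground truth, so the whole
chain is testable end to end. The 29 published DE circRNAs ship as a
packaged reference table. See `docs/methods.md` for models, parameters
and limitations.

## Worked example

The numbered scripts under `analysis/` run the study end to end on
synthetic data (seed 1), writing tables to `results/`:

```sh
python analysis/01_simulate_study.py
python analysis/02_differential_expression.py
python analysis/03_binding_sites.py
python analysis/04_cerna_networks.py
python analysis/05_enrichment.py
python analysis/06_qpcr_concordance.py
```

Output (abridged):

```
simulated 110 features, 10 planted triples, 20 planted sites -> results/study
mrna    :  11 DE of   60 features; planted recovered 10/10
circrna :   7 DE of   15 features; planted recovered 5/5
published circRNA screen (packaged table): 29 DE (21 up, 8 down) at p < 0.05
20 sites passed thresholds; seed classes: {'8mer': 20}
planted-site recall: 20/20 (100.0%), positions exact
10 candidate triples, 10 pass the ceRNA mechanism filter; network: 30 nodes, 20 edges
planted-triple precision 1.00, recall 1.00
  GO:0000001 [BP] synthetic term 01: k=10/12, p=8.75e-10 (adj 2.19e-08)
30 genes quantified; 30 concordant (+) with the sequencing screen
  circ_0001    RQ(day42) =   3.95 ** (+)
```

Reading the numbers: the DE screens recover every planted effect (e.g.
11 mRNA calls include the 10 planted plus one borderline false
positive); the site scanner finds all 20 planted 8mer sites at exact
coordinates; the triple join plus mechanism filter reconstructs all 10
planted sponge/miRNA/mRNA triples with no false triples; the planted GO
term dominates enrichment; and every planted gene's qPCR fold change
(RQ ≈ 4 or ≈ 0.25, i.e. ±2 on the log2 scale) is significant and
concordant with sequencing.

The same pipeline is scriptable via the `cerna` CLI
(`cerna run-all --seed 1 --out results/run`), with subcommands
`simulate`, `de`, `sites`, `net`, `enrich` and `qpcr` for the individual
stages on files.

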