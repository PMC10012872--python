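"""End-to-end pipeline driver over the synthetic study design.

Stages: simulate -> differential expression (per assay) -> binding sites
-> ceRNA triples (+ mechanism filter) -> GO enrichment -> qPCR
concordance. Every stage writes a TSV under the output directory and the
run ends with a JSON manifest (seed, package version, per-stage row
counts); a rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, cerna, enrich, qpcr, sitescan
from .diffexpr import PROFILES, de_table
from .io import write_fasta, write_ground_truth, write_tsv
from .simdata import (
    GroundTruth,
    SimulationConfig,
    simulate_counts,
    simulate_ct,
    simulate_sequences,
)

__all__ = [
    "PipelineConfig",
    "run_all",
    "simulate_gomap",
    "planted_triple_metrics",
    "run_recovery",
]

logger = logging.getLogger(__name__)

TARGET_CLASS_OF_ASSAY = {
    "mrna": "mRNA_3UTR",
    "lncrna": "lncRNA",
    "circrna": "circRNA",
}


@dataclass
class PipelineConfig:
    """Run configuration: simulation design, thresholds and output paths."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    outdir: str | Path = "results/pipeline"
    min_score: float = sitescan.DEFAULT_MIN_SCORE
    max_energy: float = sitescan.DEFAULT_MAX_ENERGY
    mechanism: bool = True
    n_go_terms: int = 25
    top_terms: int = 30

    def __post_init__(self) -> None:
        if self.min_score <= 0:
            raise ValueError("min_score must be positive")
        if self.max_energy > 0:
            raise ValueError("max_energy must be <= 0 kcal/mol")


def simulate_gomap(
    truth: GroundTruth, config: SimulationConfig, n_terms: int = 25
) -> pd.DataFrame:
    """Synthetic gene -> GO mapping over the mRNA universe.

    Random flat terms (no DAG) across BP/CC/MF; the first term is enriched
    for planted-triple mRNAs so network enrichment has signal to find.
    Deterministic given (config, seed).
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    genes = list(truth.features["mrna"])
    planted = [t.mrna for t in truth.planted_triples]
    rows = []
    namespaces = ["BP", "CC", "MF"]
    for i in range(1, n_terms + 1):
        go_id = f"GO:{i:07d}"
        ns = namespaces[(i - 1) % 3]
        term = f"synthetic term {i:02d}"
        if i == 1 and planted:
            members = set(planted)
            extra = max(1, len(genes) // 20)
            members |= set(rng.choice(genes, size=extra, replace=False))
        else:
            size = int(rng.integers(3, max(4, len(genes) // 3)))
            members = set(rng.choice(genes, size=size, replace=False))
        for g in sorted(members):
            rows.append((g, go_id, term, ns))
    return pd.DataFrame(rows, columns=["gene", "go_id", "term", "namespace"])


def planted_triple_metrics(
    truth: GroundTruth, triples: pd.DataFrame
) -> dict[str, float]:
    """Precision/recall of recovered (sponge, miRNA, mRNA) identities."""
    found = {
        (r["sponge"], r["mirna"], r["mrna"]) for _, r in triples.iterrows()
    }
    planted = {(t.sponge, t.mirna, t.mrna) for t in truth.planted_triples}
    tp = len(found & planted)
    precision = tp / len(found) if found else (1.0 if not planted else 0.0)
    recall = tp / len(planted) if planted else 1.0
    return {
        "tp": tp,
        "n_found": len(found),
        "n_planted": len(planted),
        "precision": precision,
        "recall": recall,
    }


def run_recovery(
    sim: SimulationConfig,
    min_score: float = sitescan.DEFAULT_MIN_SCORE,
    max_energy: float = sitescan.DEFAULT_MAX_ENERGY,
) -> tuple[dict[str, float], pd.DataFrame, GroundTruth]:
    """simulate -> de -> sites -> triples -> mechanism filter, in memory.

    Returns the planted-triple recovery metrics, the filtered triple table
    and the ground truth. This is the computational core of run_all without
    file output, used by the recovery analyses.
    """
    seqs, truth = simulate_sequences(sim)
    counts = simulate_counts(truth, sim)
    de_tables = {a: de_table(counts[a], PROFILES[a]) for a in counts}
    site_frames = [
        sitescan.predict_targets(
            seqs["mirna"], seqs[assay], TARGET_CLASS_OF_ASSAY[assay],
            min_score, max_energy,
        )
        for assay in ("circrna", "lncrna", "mrna")
    ]
    sites = pd.concat(site_frames, ignore_index=True)
    triples = cerna.find_triples(sites, de_tables)
    filtered = cerna.mechanism_filter(triples)
    return planted_triple_metrics(truth, filtered), filtered, truth


def run_all(config: PipelineConfig) -> Path:
    """Execute all stages, writing TSVs and a manifest under ``outdir``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "flycerna",
        "version": __version__,
        "seed": config.sim.seed,
        "stages": {},
    }

    current = {"name": "init"}

    def stage(name):
        current["name"] = name
        logger.info("[%s] running", name)
        return manifest["stages"].setdefault(name, {})

    try:
        rec = stage("simulate")
        seqs, truth = simulate_sequences(config.sim)
        counts = simulate_counts(truth, config.sim)
        ct = simulate_ct(truth, config.sim)
        gomap = simulate_gomap(truth, config.sim, config.n_go_terms)
        for assay, seq_map in seqs.items():
            write_fasta(out / f"{assay}.fasta", seq_map)
        design = config.sim.design().reset_index()
        write_tsv(design, out / "design.tsv")
        for assay, cm in counts.items():
            write_tsv(
                cm.counts.rename_axis("feature").reset_index(),
                out / f"counts_{assay}.tsv",
            )
        write_tsv(ct, out / "ct.tsv")
        write_tsv(gomap, out / "go_map.tsv")
        write_ground_truth(out / "ground_truth.json", truth)
        rec["n_features"] = int(sum(len(v) for v in seqs.values()))
        rec["n_planted_triples"] = len(truth.planted_triples)

        rec = stage("de")
        de_tables = {}
        for assay, cm in counts.items():
            de_tables[assay] = de_table(cm, PROFILES[assay])
            write_tsv(de_tables[assay], out / f"de_{assay}.tsv")
        rec["n_de"] = {
            a: int((t["direction"] != "ns").sum()) for a, t in de_tables.items()
        }

        rec = stage("sites")
        frames = [
            sitescan.predict_targets(
                seqs["mirna"], seqs[assay], TARGET_CLASS_OF_ASSAY[assay],
                config.min_score, config.max_energy,
            )
            for assay in ("circrna", "lncrna", "mrna")
        ]
        sites = pd.concat(frames, ignore_index=True)
        write_tsv(sites, out / "sites.tsv")
        rec["n_sites"] = len(sites)

        rec = stage("net")
        triples = cerna.find_triples(sites, de_tables)
        write_tsv(triples, out / "triples_unfiltered.tsv")
        filtered = cerna.mechanism_filter(triples) if config.mechanism else triples
        write_tsv(filtered, out / "triples.tsv")
        edges, nodes = cerna.export_network(filtered)
        write_tsv(edges, out / "network_edges.tsv")
        write_tsv(nodes, out / "network_nodes.tsv")
        rec["n_triples"] = len(filtered)
        rec["n_edges"] = len(edges)
        rec["recovery"] = planted_triple_metrics(truth, filtered)

        rec = stage("enrich")
        targets = sorted(set(filtered["mrna"]))
        if targets:
            res = enrich.hypergeom_enrich(targets, gomap)
            res = enrich.top_terms(res, config.top_terms)
        else:
            res = pd.DataFrame(columns=enrich.RESULT_COLUMNS)
        write_tsv(res, out / "enrichment.tsv")
        rec["n_terms"] = len(res)

        rec = stage("qpcr")
        rq = qpcr.delta_delta_ct(ct)
        summary = qpcr.group_test(rq)
        all_de = pd.concat(de_tables.values(), ignore_index=True)
        summary = qpcr.concordance(summary, all_de)
        write_tsv(rq, out / "rq.tsv")
        write_tsv(summary, out / "rq_summary.tsv")
        rec["n_genes"] = len(summary)
        rec["n_concordant"] = int(summary["concordant"].fillna(False).sum())
    except Exception as err:
        raise RuntimeError(
            f"pipeline stage {current['name']!r} failed: {err}"
        ) from err

    with open(out / "manifest.json", "w", newline="\n") as fh:
        json.dump(manifest, fh, indent=1)  # insertion order = stage order
        fh.write("\n")
    return out
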