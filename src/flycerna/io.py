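"""Shared readers/writers and the packaged DE-circRNA reference table.

All TSV writers emit a header, tab delimiters, no trailing whitespace and
"\\n" line endings, so outputs are byte-stable across platforms. FASTA
parsing goes through Bio.SeqIO with strict post-validation (duplicate ids,
empty sequences and non-IUPAC characters are rejected).
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio import SeqIO

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_tsv",
    "write_tsv",
    "load_table2",
    "classify_table2",
    "read_counts",
    "write_ground_truth",
]

IUPAC_NA = set("ACGTURYSWKMBDHVN")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Ordered id -> uppercase sequence mapping; wrapping-agnostic.

    Rejects duplicate ids, empty sequences and non-IUPAC characters,
    naming the offending record.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for FASTA id {rec.id!r} in {path}")
        bad = set(seq) - IUPAC_NA
        if bad:
            raise ValueError(
                f"non-IUPAC characters {sorted(bad)} in record {rec.id!r} of {path}"
            )
        seqs[rec.id] = seq
    return seqs


def write_fasta(path: str | Path, seqs: dict[str, str], width: int = 70) -> None:
    """Write sequences wrapped at ``width`` with LF line endings."""
    with open(path, "w", newline="\n") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def load_table2() -> pd.DataFrame:
    """Packaged table of the 29 DE circRNAs (log2 fold change, raw p).

    Fold-change signs follow the published up/down arrows; circBase ids
    are empty where none was listed.
    """
    ref = resources.files("flycerna.data").joinpath("table2_de_circrnas.tsv")
    with resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t", dtype={"circbase_id": "string"})
    required = {"circ_id", "log2fc", "p_value", "source_gene"}
    if not required.issubset(df.columns):
        raise ValueError("malformed DE-circRNA fixture: missing columns")
    if df["circ_id"].isna().any() or df["log2fc"].isna().any() or df[
        "p_value"
    ].isna().any():
        raise ValueError("malformed DE-circRNA fixture: missing values")
    return df


def classify_table2(
    fixture: pd.DataFrame, p_cutoff: float = 0.05
) -> tuple[int, int, int]:
    """(total, upregulated, downregulated) DE counts at ``p < p_cutoff``."""
    sig = fixture[fixture["p_value"] < p_cutoff]
    up = int((sig["log2fc"] > 0).sum())
    down = int((sig["log2fc"] < 0).sum())
    return len(sig), up, down


def read_counts(counts_path: str | Path, design_path: str | Path):
    """Load a counts_<assay>.tsv + design.tsv pair into a CountMatrix."""
    from .diffexpr import CountMatrix

    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    design = pd.read_csv(design_path, sep="\t", index_col=0)
    design = design.loc[[s for s in design.index if s in counts.columns]]
    return CountMatrix(counts, design)


def write_ground_truth(path: str | Path, truth) -> None:
    with open(path, "w", newline="\n") as fh:
        json.dump(truth.to_jsonable(), fh, indent=1, sort_keys=True)
        fh.write("\n")
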