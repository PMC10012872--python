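"""miRanda-style miRNA binding-site prediction.

Three layers, mirroring how seed-match target predictors are organized:

1. ``find_seed_sites`` — exact Watson-Crick seed anchors. The seed is miRNA
   positions 2-8 (5'->3'); classes follow the canonical hierarchy:
   8mer      : WC pairing of positions 2-8 AND an A in the target opposite
               position 1;
   7mer-m8   : WC pairing of positions 2-8, no A1;
   7mer-A1   : WC pairing of positions 2-7 plus the A1, position 8 unpaired;
   6mer      : WC pairing of positions 2-7 only.
   G:U wobbles are not accepted inside the seed. Site coordinates are the
   8-nt target window opposite miRNA positions 1-8, 1-based inclusive on
   the target's 5'->3' strand.

2. ``extend_alignment`` — local antiparallel hybrid alignment (Gotoh affine
   gaps) of the full miRNA against the anchor window +/-30 nt: match +5,
   G:U wobble +2, mismatch -3, gap open -9, gap extend -4, with all
   substitution scores doubled at miRNA seed positions 2-8 (5' dominance).

3. ``duplex_energy`` — nearest-neighbor RNA:RNA free energy of the aligned
   duplex: helix initiation + stacking terms from a bundled approximate
   Turner-style table (G:U stacks included) + a length-linear penalty per
   interior loop/bulge. More negative = more stable, kcal/mol.

circRNAs are scanned with the first ``L-1`` nucleotides appended (L = miRNA
length) so back-splice-spanning sites are findable; coordinates are
reported modulo the sequence length.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SeedAnchor",
    "find_seed_sites",
    "extend_alignment",
    "duplex_energy",
    "predict_targets",
    "DEFAULT_MIN_SCORE",
    "DEFAULT_MAX_ENERGY",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_SCORE = 140.0
DEFAULT_MAX_ENERGY = -10.0

MATCH = 5.0
WOBBLE = 2.0
MISMATCH = -3.0
GAP_OPEN = -9.0
GAP_EXTEND = -4.0
SEED_MULT = 2.0  # applied to miRNA positions 2-8

_COMP = {"A": "U", "C": "G", "G": "C", "U": "A"}
_WC = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
_GU = {("G", "U"), ("U", "G")}

DUPLEX_INITIATION = 4.09  # kcal/mol
LOOP_BASE = 2.0
LOOP_PER_NT = 0.4

# Watson-Crick nearest-neighbor stacks, 37 C, kcal/mol (Xia et al. style).
# Key: 5'WX3' paired antiparallel with 3'ZY5' -> ((W, Z), (X, Y)).
_WC_STACKS = {
    (("A", "U"), ("A", "U")): -0.93,
    (("A", "U"), ("U", "A")): -1.10,
    (("U", "A"), ("A", "U")): -1.33,
    (("C", "G"), ("U", "A")): -2.08,
    (("C", "G"), ("A", "U")): -2.11,
    (("G", "C"), ("U", "A")): -2.24,
    (("G", "C"), ("A", "U")): -2.35,
    (("C", "G"), ("G", "C")): -2.36,
    (("G", "C"), ("G", "C")): -3.26,
    (("G", "C"), ("C", "G")): -3.42,
}
# Approximate G:U-containing stacks (one wobble pair).
_GU_STACKS = {
    (("A", "U"), ("G", "U")): -0.55,
    (("A", "U"), ("U", "G")): -1.36,
    (("C", "G"), ("G", "U")): -1.41,
    (("C", "G"), ("U", "G")): -2.11,
    (("G", "C"), ("G", "U")): -1.53,
    (("G", "C"), ("U", "G")): -2.51,
    (("U", "A"), ("G", "U")): -1.00,
    (("U", "A"), ("U", "G")): -1.27,
    (("G", "U"), ("A", "U")): -1.27,
    (("U", "G"), ("A", "U")): -1.00,
}
_GU_FALLBACK = -1.0   # single-wobble stack not in the table
_GUGU_FALLBACK = 0.5  # tandem-wobble stacks are destabilizing on average


def _build_stack_table() -> dict[tuple[tuple[str, str], tuple[str, str]], float]:
    """Complete the stack table over all 36 pair combinations.

    Symmetry: rotating a duplex 180 degrees maps 5'WX3'/3'ZY5' onto
    5'YZ3'/3'XW5', so both keys share one value.
    """
    pairs = [("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")]
    table: dict = {}
    seeded = {**_WC_STACKS, **_GU_STACKS}
    for key, val in seeded.items():
        (w, z), (x, y) = key
        table[key] = val
        table[((y, x), (z, w))] = val
    for p1 in pairs:
        for p2 in pairs:
            if (p1, p2) in table:
                continue
            n_gu = (tuple(p1) in _GU) + (tuple(p2) in _GU)
            table[(p1, p2)] = _GUGU_FALLBACK if n_gu == 2 else _GU_FALLBACK
    return table


STACK_TABLE = _build_stack_table()


def normalize_rna(seq: str, name: str = "sequence") -> str:
    """Uppercase, DNA T converted to U (logged); rejects other characters."""
    up = seq.upper()
    if "T" in up:
        logger.warning("%s contains T; converting DNA to RNA alphabet", name)
        up = up.replace("T", "U")
    bad = set(up) - set("ACGU")
    if bad:
        raise ValueError(f"{name}: non-RNA characters {sorted(bad)}")
    return up


@dataclass(frozen=True)
class SeedAnchor:
    """One seed match: 1-based inclusive coords of the 8-nt target window
    opposite miRNA positions 1-8, plus the seed class."""

    start: int
    end: int
    seed_class: str


def find_seed_sites(mirna: str, target: str) -> list[SeedAnchor]:
    """All seed anchors of ``mirna`` on ``target`` (both 5'->3' RNA)."""
    mirna = normalize_rna(mirna, "miRNA")
    target = normalize_rna(target, "target")
    if len(mirna) < 19:
        raise ValueError("miRNA must be >= 19 nt")
    # Pairing geometry: miRNA position i pairs target position e-(i-1)
    # (0-based e opposite position 1). Positions 2-7 complementary means
    # target[e-6:e] equals revcomp(miRNA[1:7]).
    core = "".join(_COMP[b] for b in mirna[1:7])[::-1]
    comp_m8 = _COMP[mirna[7]]
    anchors: list[SeedAnchor] = []
    q = target.find(core, 1)
    while q != -1:
        e = q + 6
        if e <= len(target) - 1 and e >= 7:
            m8 = target[e - 7] == comp_m8
            a1 = target[e] == "A"
            if m8 and a1:
                cls = "8mer"
            elif m8:
                cls = "7mer-m8"
            elif a1:
                cls = "7mer-A1"
            else:
                cls = "6mer"
            anchors.append(SeedAnchor(e - 6, e + 1, cls))
        q = target.find(core, q + 1)
    return anchors


def _pair_score(m_base: str, t_base: str, m_pos: int) -> float:
    if (m_base, t_base) in _WC:
        s = MATCH
    elif (m_base, t_base) in _GU:
        s = WOBBLE
    else:
        s = MISMATCH
    if 2 <= m_pos <= 8:
        s *= SEED_MULT
    return s


def extend_alignment(
    mirna: str, target: str, anchor: SeedAnchor, flank: int = 30
) -> tuple[float, tuple[str, str]]:
    """Best local hybrid alignment around a seed anchor.

    Returns ``(score, (target_row, mirna_row))`` where the two rows are the
    aligned duplex: target 5'->3' on top, miRNA 3'->5' below, '-' for gaps
    and leading/trailing unaligned parts trimmed.
    """
    mirna = normalize_rna(mirna, "miRNA")
    target = normalize_rna(target, "target")
    lo = max(0, anchor.start - 1 - flank)
    hi = min(len(target), anchor.end + flank)
    window = target[lo:hi]
    mir_rev = mirna[::-1]  # 3'->5', so both strings read in pairing order
    L = len(mirna)
    n, m = len(window), len(mir_rev)
    NEG = -1e9
    M = [[0.0] * (m + 1) for _ in range(n + 1)]  # pair state (local)
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in miRNA row
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in target row
    ptrM = [[0] * (m + 1) for _ in range(n + 1)]
    ptrX = [[0] * (m + 1) for _ in range(n + 1)]
    ptrY = [[0] * (m + 1) for _ in range(n + 1)]
    best, best_ij = 0.0, None
    # Pre-compute substitution rows per miRNA column (position-dependent).
    sub_cols = [
        {b: _pair_score(mir_rev[j - 1], b, L - j + 1) for b in "ACGU"}
        for j in range(1, m + 1)
    ]
    for i in range(1, n + 1):
        tb = window[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        for j in range(1, m + 1):
            sub = sub_cols[j - 1][tb]
            dm, dx, dy = Mp[j - 1], Xp[j - 1], Yp[j - 1]
            if dm >= dx and dm >= dy:
                val, k = dm + sub, 0
            elif dx >= dy:
                val, k = dx + sub, 1
            else:
                val, k = dy + sub, 2
            if val < 0.0:
                Mi[j], ptrM[i][j] = 0.0, -1
            else:
                Mi[j], ptrM[i][j] = val, k
            xo, xe = Mp[j] + GAP_OPEN, Xp[j] + GAP_EXTEND
            if xo >= xe:
                Xi[j], ptrX[i][j] = xo, 0
            else:
                Xi[j], ptrX[i][j] = xe, 1
            yo, ye = Mi[j - 1] + GAP_OPEN, Yi[j - 1] + GAP_EXTEND
            if yo >= ye:
                Yi[j], ptrY[i][j] = yo, 0
            else:
                Yi[j], ptrY[i][j] = ye, 2
            if Mi[j] > best:
                best, best_ij = Mi[j], (i, j)
    if best_ij is None:
        return 0.0, ("", "")
    # Traceback from the best M cell.
    i, j, state = *best_ij, 0
    top, bot = [], []
    while i > 0 and j > 0:
        if state == 0:
            prev = ptrM[i][j]
            top.append(window[i - 1])
            bot.append(mir_rev[j - 1])
            i, j = i - 1, j - 1
            if prev == -1 or (prev == 0 and M[i][j] == 0.0):
                break
            state = prev
        elif state == 1:
            prev = ptrX[i][j]
            top.append(window[i - 1])
            bot.append("-")
            i -= 1
            state = prev
        else:
            prev = ptrY[i][j]
            top.append("-")
            bot.append(mir_rev[j - 1])
            j -= 1
            state = prev
    return float(best), ("".join(reversed(top)), "".join(reversed(bot)))


def _is_pair(a: str, b: str) -> bool:
    return (a, b) in _WC or (a, b) in _GU


def duplex_energy(target_row: str, mirna_row: str) -> float:
    """Nearest-neighbor free energy (kcal/mol) of an aligned duplex.

    ``target_row`` is 5'->3', ``mirna_row`` 3'->5', equal length, '-' for
    gaps. dG = initiation + sum of stacks over adjacent paired columns +
    (LOOP_BASE + LOOP_PER_NT * n_unpaired) per interior loop/bulge.
    Raises ValueError when the duplex has no helix of >= 2 base pairs.
    """
    if len(target_row) != len(mirna_row):
        raise ValueError("aligned rows must have equal length")
    paired = [
        i
        for i in range(len(target_row))
        if target_row[i] != "-" and mirna_row[i] != "-"
        and _is_pair(target_row[i], mirna_row[i])
    ]
    if not any(b - a == 1 for a, b in zip(paired, paired[1:])):
        raise ValueError("duplex has no helix of length >= 2")
    dg = DUPLEX_INITIATION
    for a, b in zip(paired, paired[1:]):
        if b - a == 1:
            key = ((target_row[a], mirna_row[a]), (target_row[b], mirna_row[b]))
            dg += STACK_TABLE[key]
        else:
            unpaired = sum(
                (1 if target_row[i] != "-" else 0) + (1 if mirna_row[i] != "-" else 0)
                for i in range(a + 1, b)
            )
            dg += LOOP_BASE + LOOP_PER_NT * unpaired
    return float(dg)


def _scan_one(
    mirna_id: str,
    mirna_seq: str,
    target_id: str,
    target_seq: str,
    target_class: str,
) -> list[dict]:
    circular = target_class == "circRNA"
    true_len = len(target_seq)
    scan_seq = target_seq
    if circular and true_len > len(mirna_seq):
        scan_seq = target_seq + target_seq[: len(mirna_seq) - 1]
    rows = []
    seen: set[tuple[int, int]] = set()
    for anchor in find_seed_sites(mirna_seq, scan_seq):
        start = ((anchor.start - 1) % true_len) + 1
        end = ((anchor.end - 1) % true_len) + 1
        if (start, end) in seen:
            continue
        seen.add((start, end))
        score, (top, bot) = extend_alignment(mirna_seq, scan_seq, anchor)
        try:
            energy = duplex_energy(top, bot)
        except ValueError:
            continue
        rows.append(
            {
                "mirna": mirna_id,
                "target": target_id,
                "target_class": target_class,
                "start": start,
                "end": end,
                "ext_start": anchor.start,  # extended-axis coords for overlap
                "ext_end": anchor.end,
                "seed_class": anchor.seed_class,
                "score": score,
                "energy": energy,
            }
        )
    return rows


def _resolve_overlaps(rows: list[dict]) -> list[dict]:
    """Greedy per-(miRNA, target): best score first, then non-overlapping;
    equal scores break toward the lower start coordinate."""
    rows = sorted(rows, key=lambda r: (-r["score"], r["ext_start"]))
    kept: list[dict] = []
    for r in rows:
        if all(
            r["ext_end"] < k["ext_start"] or r["ext_start"] > k["ext_end"]
            for k in kept
        ):
            kept.append(r)
    return kept


def predict_targets(
    mirnas: dict[str, str],
    targets: dict[str, str],
    target_class: str,
    min_score: float = DEFAULT_MIN_SCORE,
    max_energy: float = DEFAULT_MAX_ENERGY,
) -> pd.DataFrame:
    """Binding-site table for all miRNA x target combinations.

    Sites must reach ``score >= min_score`` and ``energy <= max_energy``.
    Overlapping sites of one (miRNA, target) pair are resolved greedily by
    score. Output is sorted by (target, start, mirna).
    """
    if target_class not in {"mRNA_3UTR", "circRNA", "lncRNA"}:
        raise ValueError(f"unknown target class {target_class!r}")
    cols = [
        "mirna", "target", "target_class", "start", "end",
        "seed_class", "score", "energy",
    ]
    if not mirnas or not targets:
        warnings.warn("empty input set; returning empty site table", stacklevel=2)
        return pd.DataFrame(columns=cols)
    out: list[dict] = []
    for tid in targets:
        for mid in mirnas:
            rows = _scan_one(mid, mirnas[mid], tid, targets[tid], target_class)
            rows = [
                r for r in rows
                if r["score"] >= min_score and r["energy"] <= max_energy
            ]
            out.extend(_resolve_overlaps(rows))
    df = pd.DataFrame(out, columns=cols + ["ext_start", "ext_end"])[cols]
    return df.sort_values(["target", "start", "mirna"], kind="stable").reset_index(
        drop=True
    )
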