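"""Synthetic study generator: sequences, counts and qPCR tables with
planted ceRNA structure and exported ground truth.

The generator emulates the two-age study design: RNA-seq (mRNA, lncRNA,
circRNA) with two biological replicates per condition and miRNA-seq with
five, negative-binomial counts with planted log2 fold changes, and planted
sponge/miRNA/mRNA triples whose expression trends are sign-consistent with
the ceRNA mechanism (sponge and mRNA co-directional, miRNA opposite).

Planted binding sites are full-length reverse complements of the miRNA with
the canonical A opposite miRNA position 1; the recorded ground-truth
coordinates are the 8-nt seed window (miRNA positions 1-8), which is an
exact 8mer site. Background sequence composition is i.i.d. uniform A/C/G/U.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexpr import CountMatrix

__all__ = [
    "SimulationConfig",
    "PlantedSite",
    "PlantedTriple",
    "GroundTruth",
    "simulate_sequences",
    "simulate_counts",
    "simulate_ct",
    "sample_nb",
]

RNA_ALPHABET = np.array(list("ACGU"))
_COMP = str.maketrans("ACGU", "UGCA")

ASSAY_CLASSES = {
    "mrna": "mRNA_3UTR",
    "lncrna": "lncRNA",
    "circrna": "circRNA",
    "mirna": "miRNA",
}

REFERENCE_GENE = "rp49"


def revcomp(seq: str) -> str:
    """Reverse complement of an RNA string (A/C/G/U)."""
    return seq.translate(_COMP)[::-1]


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic generator.

    Replicate defaults follow the study (2 biological replicates for
    RNA-seq, 5 for miRNA-seq); the planted effect size is log2 units and
    ``dispersion`` is the NB alpha with variance mu + alpha*mu^2.
    """

    n_mrna: int = 60
    n_lncrna: int = 15
    n_circrna: int = 15
    n_mirna: int = 20
    n_triples_planted: int = 10
    reps_rnaseq: int = 2
    reps_mirnaseq: int = 5
    baseline_mean: float = 500.0
    log2fc_effect: float = 2.0
    dispersion: float = 0.05
    utr_length: int = 600
    sponge_length: int = 800
    mirna_length: int = 22
    sites_per_pair: int = 1
    ct_replicates: int = 3
    ct_noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_mrna", "n_lncrna", "n_circrna", "n_mirna", "reps_rnaseq",
            "reps_mirnaseq", "utr_length", "sponge_length", "mirna_length",
            "sites_per_pair", "ct_replicates",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_triples_planted < 0:
            raise ValueError("n_triples_planted must be >= 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        cap = min(self.n_circrna + self.n_lncrna, self.n_mirna, self.n_mrna)
        if self.n_triples_planted > cap:
            raise ValueError(
                f"n_triples_planted={self.n_triples_planted} exceeds "
                f"min(sponges, miRNAs, mRNAs)={cap}"
            )
        if self.mirna_length > min(self.utr_length, self.sponge_length):
            raise ValueError("planted site longer than its target sequence")

    def feature_ids(self) -> dict[str, list[str]]:
        return {
            "mrna": [f"mRNA_{i:04d}" for i in range(1, self.n_mrna + 1)],
            "lncrna": [f"lnc_{i:04d}" for i in range(1, self.n_lncrna + 1)],
            "circrna": [f"circ_{i:04d}" for i in range(1, self.n_circrna + 1)],
            "mirna": [f"miR_{i:04d}" for i in range(1, self.n_mirna + 1)],
        }

    def design(self) -> pd.DataFrame:
        """Sample design table across both assays and conditions."""
        rows = []
        for cond in ("day7", "day42"):
            for r in range(1, self.reps_rnaseq + 1):
                rows.append((f"{cond}_rna_r{r}", cond, "rnaseq", r))
            for r in range(1, self.reps_mirnaseq + 1):
                rows.append((f"{cond}_mir_r{r}", cond, "mirnaseq", r))
        return pd.DataFrame(
            rows, columns=["sample", "condition", "assay", "replicate"]
        ).set_index("sample")


@dataclass(frozen=True)
class PlantedSite:
    mirna: str
    target: str
    start: int  # 1-based inclusive, 8-nt seed window (miRNA positions 1-8)
    end: int
    seed_class: str = "8mer"


@dataclass(frozen=True)
class PlantedTriple:
    sponge: str
    sponge_class: str
    mirna: str
    mrna: str
    directions: tuple[str, str, str]  # (sponge, miRNA, mRNA)


@dataclass
class GroundTruth:
    """Exported truth: planted triples/sites and true log2 fold changes."""

    planted_triples: list[PlantedTriple] = field(default_factory=list)
    planted_sites: list[PlantedSite] = field(default_factory=list)
    true_log2fc: dict[str, float] = field(default_factory=dict)
    features: dict[str, list[str]] = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        return {
            "planted_triples": [vars(t) | {"directions": list(t.directions)}
                                for t in self.planted_triples],
            "planted_sites": [vars(s) for s in self.planted_sites],
            "true_log2fc": self.true_log2fc,
            "features": self.features,
        }


def _rng_children(seed: int) -> dict[str, np.random.Generator]:
    seq = np.random.SeedSequence(seed)
    kids = seq.spawn(3)
    return {
        "sequences": np.random.default_rng(kids[0]),
        "counts": np.random.default_rng(kids[1]),
        "ct": np.random.default_rng(kids[2]),
    }


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(RNA_ALPHABET, size=length))


def sample_nb(
    mean: float | np.ndarray,
    dispersion: float,
    size: int | tuple,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw NB counts with variance mu + dispersion*mu^2 (0 -> Poisson)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def _plant_positions(
    rng: np.random.Generator, target_len: int, site_len: int, n_sites: int,
    occupied: list[tuple[int, int]],
) -> list[int]:
    """Non-overlapping 0-based start positions for planted sites."""
    starts: list[int] = []
    taken = list(occupied)
    for _ in range(n_sites):
        for _attempt in range(200):
            s = int(rng.integers(0, target_len - site_len + 1))
            if all(s + site_len <= a or s >= b for a, b in taken):
                starts.append(s)
                taken.append((s, s + site_len))
                break
        else:  # pragma: no cover - only under absurdly dense planting
            raise ValueError("could not place non-overlapping planted sites")
    return starts


def simulate_sequences(
    config: SimulationConfig,
) -> tuple[dict[str, dict[str, str]], GroundTruth]:
    """Random-composition RNA sequences with planted miRNA sites.

    Returns ``(sequences, truth)`` where ``sequences`` maps assay ->
    {feature id -> sequence}. For each planted (miRNA, target) pair the
    target carries ``sites_per_pair`` full-complement sites whose recorded
    coordinates are the 8mer seed window (reverse complement of miRNA
    positions 2-8 plus an A opposite position 1).
    """
    rng = _rng_children(config.seed)["sequences"]
    ids = config.feature_ids()
    lengths = {
        "mrna": config.utr_length,
        "lncrna": config.sponge_length,
        "circrna": config.sponge_length,
        "mirna": config.mirna_length,
    }
    seqs: dict[str, dict[str, str]] = {
        assay: {fid: _random_seq(rng, lengths[assay]) for fid in ids[assay]}
        for assay in ("mrna", "lncrna", "circrna", "mirna")
    }

    truth = GroundTruth(features=ids)
    truth.true_log2fc = {
        fid: 0.0 for assay in ids for fid in ids[assay]
    }

    # Sponges alternate circRNA / lncRNA so both classes are exercised.
    sponge_pool: list[tuple[str, str]] = []
    ic = il = 0
    while ic < config.n_circrna or il < config.n_lncrna:
        if ic < config.n_circrna:
            sponge_pool.append((ids["circrna"][ic], "circRNA"))
            ic += 1
        if il < config.n_lncrna:
            sponge_pool.append((ids["lncrna"][il], "lncRNA"))
            il += 1

    occupied: dict[str, list[tuple[int, int]]] = {}
    for t in range(config.n_triples_planted):
        sponge, sponge_class = sponge_pool[t]
        mirna = ids["mirna"][t]
        mrna = ids["mrna"][t]
        directions = ("up", "down", "up") if t % 2 == 0 else ("down", "up", "down")
        truth.planted_triples.append(
            PlantedTriple(sponge, sponge_class, mirna, mrna, directions)
        )
        eff = config.log2fc_effect
        sign = 1.0 if directions[0] == "up" else -1.0
        truth.true_log2fc[sponge] = sign * eff
        truth.true_log2fc[mirna] = -sign * eff
        truth.true_log2fc[mrna] = sign * eff

        mir_seq = seqs["mirna"][mirna]
        # Full site: reverse complement of positions 2..L, then A opposite
        # position 1 at the site's 3' end. Its last 8 nt are the 8mer.
        site_seq = revcomp(mir_seq[1:]) + "A"
        L = len(site_seq)
        sponge_assay = "circrna" if sponge_class == "circRNA" else "lncrna"
        for target_assay, target in ((sponge_assay, sponge), ("mrna", mrna)):
            tgt_seq = seqs[target_assay][target]
            starts = _plant_positions(
                rng, len(tgt_seq), L, config.sites_per_pair,
                occupied.setdefault(target, []),
            )
            for s in starts:
                tgt_seq = tgt_seq[:s] + site_seq + tgt_seq[s + L:]
                # 8mer seed window = last 8 nt of the planted site.
                truth.planted_sites.append(
                    PlantedSite(mirna, target, s + L - 7, s + L, "8mer")
                )
            seqs[target_assay][target] = tgt_seq
    return seqs, truth


def simulate_counts(
    truth: GroundTruth, config: SimulationConfig
) -> dict[str, CountMatrix]:
    """NB count matrices per assay honouring the planted log2 fold changes.

    Per-feature baselines are log2-uniform in [baseline/2, 2*baseline]
    (geometric mean = ``baseline_mean``) and per-sample size factors are
    log-uniform in [0.7, 1.4] so normalization is non-trivial. Deterministic
    given (config, seed).
    """
    rng = _rng_children(config.seed)["counts"]
    design = config.design()
    out: dict[str, CountMatrix] = {}
    for assay in ("mrna", "lncrna", "circrna", "mirna"):
        features = truth.features[assay]
        seq_assay = "mirnaseq" if assay == "mirna" else "rnaseq"
        samples = design.index[design["assay"] == seq_assay]
        sub = design.loc[samples]
        base = config.baseline_mean * 2.0 ** rng.uniform(-1, 1, size=len(features))
        sf = np.exp(
            rng.uniform(np.log(0.7), np.log(1.4), size=len(samples))
        )
        lfc = np.array([truth.true_log2fc[f] for f in features])
        is42 = (sub["condition"] == "day42").values.astype(float)
        mu = base[:, None] * 2.0 ** (lfc[:, None] * is42[None, :]) * sf[None, :]
        counts = sample_nb(mu, config.dispersion, mu.shape, rng)
        out[assay] = CountMatrix(
            pd.DataFrame(counts, index=features, columns=samples), sub
        )
    return out


def simulate_ct(
    truth: GroundTruth,
    config: SimulationConfig,
    genes: list[str] | None = None,
    ct_ref: float = 20.0,
    ct_offset: float = 5.0,
) -> pd.DataFrame:
    """qPCR cycle-threshold table for planted-triple members plus rp49.

    Per sample: Ct(ref) = ct_ref + noise, Ct(gene) = ct_ref + ct_offset
    - log2fc*[day42] + noise, so the expected ddCt between conditions is
    -log2fc and 2^-ddCt recovers the planted fold change.
    """
    rng = _rng_children(config.seed)["ct"]
    if genes is None:
        genes = sorted(
            {g for t in truth.planted_triples for g in (t.sponge, t.mirna, t.mrna)}
        )
    if REFERENCE_GENE in genes:
        raise ValueError("reference gene cannot also be a target gene")
    rows = []
    for cond in ("day7", "day42"):
        for rep in range(1, config.ct_replicates + 1):
            sample = f"{cond}_qpcr_r{rep}"
            ref_ct = ct_ref + rng.normal(0, config.ct_noise_sd)
            rows.append((sample, cond, REFERENCE_GENE, ref_ct))
            for g in genes:
                shift = -truth.true_log2fc.get(g, 0.0) if cond == "day42" else 0.0
                noise = rng.normal(0, config.ct_noise_sd) if config.ct_noise_sd else 0.0
                rows.append((sample, cond, g, ct_ref + ct_offset + shift + noise))
    return pd.DataFrame(rows, columns=["sample", "condition", "gene", "ct"])
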