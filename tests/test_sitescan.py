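"""Seed scanning, hybrid alignment scoring, duplex energies."""

import math

import numpy as np
import pytest

from flycerna import sitescan
from flycerna.sitescan import (
    DUPLEX_INITIATION,
    STACK_TABLE,
    SeedAnchor,
    duplex_energy,
    extend_alignment,
    find_seed_sites,
    predict_targets,
)
from flycerna.simdata import SimulationConfig, revcomp, simulate_sequences

COMP = {"A": "U", "U": "A", "C": "G", "G": "C"}


def oracle_seed_scan(mirna: str, target: str):
    """Exhaustive window scan, independent of the implementation.

    For each candidate position e (0-based target index opposite miRNA
    position 1), check Watson-Crick identity per position directly.
    """
    hits = []
    for e in range(7, len(target) - 1 + 1):
        if e > len(target) - 1:
            continue
        pairs = {
            i: target[e - (i - 1)] == COMP[mirna[i - 1]] for i in range(2, 9)
        }
        core = all(pairs[i] for i in range(2, 8))
        if not core:
            continue
        m8 = pairs[8]
        a1 = target[e] == "A"
        cls = (
            "8mer" if m8 and a1 else "7mer-m8" if m8 else "7mer-A1" if a1 else "6mer"
        )
        hits.append((e - 6, e + 1, cls))
    return hits


def random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))


class TestFindSeedSites:
    def test_manual_8mer_example(self):
        mirna = "A" + "GGAAUGU" + "ACGUACGUACGUAC"  # positions 2-8 = GGAAUGU
        target = "CCCC" + "ACAUUCCA" + "GGGG"
        anchors = find_seed_sites(mirna, target)
        assert anchors == [SeedAnchor(5, 12, "8mer")]

    def test_poly_a_target_has_no_anchors(self):
        mirna = "ACGUGGCAUGACGUAGCUAGCU"
        assert find_seed_sites(mirna, "A" * 100) == []

    def test_seed_class_hierarchy(self):
        mirna = "A" + "GGAAUGU" + "ACGUACGUACGUAC"
        # 7mer-m8: positions 2-8 paired, no A1.
        assert find_seed_sites(mirna, "CCCCACAUUCCGCCC")[0].seed_class == "7mer-m8"
        # 7mer-A1: positions 2-7 paired + A1, position 8 unpaired.
        assert find_seed_sites(mirna, "CCCCGCAUUCCACCC")[0].seed_class == "7mer-A1"
        # 6mer: positions 2-7 only.
        assert find_seed_sites(mirna, "CCCCGCAUUCCGCCC")[0].seed_class == "6mer"

    def test_gu_wobble_not_accepted_in_seed(self):
        mirna = "A" + "GGAAUGU" + "ACGUACGUACGUAC"
        # Replace one seed-pairing C by U (G:U wobble) -> no anchor.
        assert find_seed_sites(mirna, "CCCCACAUUUCACCC") == []

    def test_short_mirna_rejected_and_t_converted(self):
        with pytest.raises(ValueError):
            find_seed_sites("ACGUACGUACGU", "ACGU" * 30)
        mirna = "A" + "GGAAUGU" + "ACGUACGUACGUAC"
        dna = "CCCCACATTCCAGGGG"  # T for U
        assert find_seed_sites(mirna, dna)[0].seed_class == "8mer"

    def test_matches_exhaustive_oracle_on_random_pairs(self, rng):
        for _ in range(30):
            mirna = random_rna(rng, 22)
            target = random_rna(rng, 400)
            got = [(a.start, a.end, a.seed_class) for a in find_seed_sites(mirna, target)]
            assert got == oracle_seed_scan(mirna, target)

    def test_reversed_target_destroys_anchors(self, rng):
        cfg = SimulationConfig(
            n_mrna=4, n_lncrna=1, n_circrna=1, n_mirna=2, n_triples_planted=2,
            utr_length=200, sponge_length=200, seed=5,
        )
        seqs, truth = simulate_sequences(cfg)
        for site in truth.planted_sites:
            mir = seqs["mirna"][site.mirna]
            tgt = {**seqs["mrna"], **seqs["lncrna"], **seqs["circrna"]}[site.target]
            fwd = find_seed_sites(mir, tgt)
            rev = find_seed_sites(mir, tgt[::-1])
            assert any(a.start == site.start for a in fwd)
            assert not any(a.start == len(tgt) - site.end + 1 for a in rev)


class TestExtendAlignment:
    def test_perfect_complement_scores_145(self):
        mirna = "UGAGGUAGUAGGUUGUAUAGUU"  # 22 nt
        site = revcomp(mirna)
        target = "CCCCCCCCCC" + site + "CCCCCCCCCC"
        anchors = find_seed_sites(mirna, target)
        assert anchors, "perfect complement must contain a seed anchor"
        score, (top, bot) = extend_alignment(mirna, target, anchors[0])
        # match +5 everywhere, doubled at the 7 seed positions: 22*5 + 7*5.
        assert score == pytest.approx(145.0)
        assert len(top) == 22 and "-" not in top and "-" not in bot

    def test_seed_only_pairing_scores_70(self):
        # Seed pairing for positions 2-8, poly-C elsewhere on both sides so
        # nothing outside the seed can pair (G:C pairs impossible: miRNA 3'
        # region is C and target flanks are C too).
        mirna = "A" + "GGAAUGU" + "C" * 14
        target = "AAAAAAAAAA" + "ACAUUCC" + "A" + "AAAAAAAAAA"
        anchors = find_seed_sites(mirna, target)
        score, _ = extend_alignment(mirna, target, anchors[0])
        assert score == pytest.approx(70.0)

    def test_match_outside_seed_never_decreases_score(self, rng):
        mirna = random_rna(rng, 22)
        site = revcomp(mirna)
        # Mismatch at miRNA position 15 (outside seed).
        pos = len(site) - 15  # 0-based target index pairing position 15
        broken = site[:pos] + COMP[site[pos]] + site[pos + 1 :]
        flank = "C" * 10
        for variant, better in [(broken, False), (site, True)]:
            target = flank + variant + flank
            a = find_seed_sites(mirna, target)[0]
            s, _ = extend_alignment(mirna, target, a)
            if better:
                s_perfect = s
            else:
                s_broken = s
        assert s_perfect >= s_broken


class TestDuplexEnergy:
    def test_two_pair_helix_is_initiation_plus_one_stack(self):
        # 5'GC3' / 3'CG5' duplex: single stack ((G,C),(C,G)).
        dg = duplex_energy("GC", "CG")
        assert dg == pytest.approx(DUPLEX_INITIATION + STACK_TABLE[(("G", "C"), ("C", "G"))])

    def test_five_pair_helix_additivity_by_hand(self):
        top, bot = "GCAUG", "CGUAC"
        expected = DUPLEX_INITIATION + sum(
            STACK_TABLE[((top[i], bot[i]), (top[i + 1], bot[i + 1]))]
            for i in range(4)
        )
        assert duplex_energy(top, bot) == pytest.approx(expected)

    def test_appending_gc_stack_strictly_stabilizes(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 8))
            top = "".join(rng.choice(list("ACGU"), size=n))
            bot = "".join(COMP[b] for b in top)
            dg = duplex_energy(top, bot)
            dg_ext = duplex_energy(top + "G", bot + "C")
            assert dg_ext < dg

    def test_interior_loop_penalized(self):
        helix = duplex_energy("GCGC", "CGCG")
        looped = duplex_energy("GC" + "AA" + "GC", "CG" + "--" + "CG")
        assert looped > helix  # bulge destabilizes

    def test_no_helix_raises(self):
        with pytest.raises(ValueError):
            duplex_energy("ACA", "AGA")  # no two adjacent pairs

    def test_random_helix_stack_decomposition(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 12))
            top = "".join(rng.choice(list("ACGU"), size=n))
            bot = "".join(COMP[b] for b in top)
            expected = DUPLEX_INITIATION + sum(
                STACK_TABLE[((top[i], bot[i]), (top[i + 1], bot[i + 1]))]
                for i in range(n - 1)
            )
            assert duplex_energy(top, bot) == pytest.approx(expected)


class TestPredictTargets:
    def test_planted_sites_full_recall_at_defaults(self):
        cfg = SimulationConfig(
            n_mrna=8, n_lncrna=3, n_circrna=3, n_mirna=4, n_triples_planted=4,
            utr_length=300, sponge_length=300, seed=11,
        )
        seqs, truth = simulate_sequences(cfg)
        frames = []
        for assay, cls in (("mrna", "mRNA_3UTR"), ("lncrna", "lncRNA"),
                           ("circrna", "circRNA")):
            frames.append(predict_targets(seqs["mirna"], seqs[assay], cls))
        import pandas as pd

        sites = pd.concat(frames, ignore_index=True)
        found = {
            (r["mirna"], r["target"], r["start"], r["end"])
            for _, r in sites.iterrows()
        }
        for s in truth.planted_sites:
            assert (s.mirna, s.target, s.start, s.end) in found

    def test_infinite_score_threshold_empties_output(self):
        mirnas = {"m": "UGAGGUAGUAGGUUGUAUAGUU"}
        targets = {"t": "C" * 50 + revcomp(mirnas["m"]) + "C" * 50}
        out = predict_targets(mirnas, targets, "mRNA_3UTR", min_score=math.inf)
        assert out.empty

    def test_five_planted_sites_reported_exactly(self):
        """A sponge with 5 non-overlapping sites for one miRNA."""
        cfg = SimulationConfig(
            n_mrna=2, n_lncrna=1, n_circrna=1, n_mirna=1, n_triples_planted=1,
            utr_length=300, sponge_length=400, sites_per_pair=5, seed=2,
        )
        seqs, truth = simulate_sequences(cfg)
        sponge = truth.planted_triples[0].sponge
        cls = truth.planted_triples[0].sponge_class
        assay = "circrna" if cls == "circRNA" else "lncrna"
        out = predict_targets(seqs["mirna"], {sponge: seqs[assay][sponge]}, cls)
        assert len(out) == 5

    def test_circular_junction_site_found(self):
        mirna = "UGAGGUAGUAGGUUGUAUAGUU"
        site = revcomp(mirna)
        # Split the site across the back-splice junction: last 4 nt at the
        # sequence start, first 18 at the end, so even the 8-nt seed window
        # spans the junction.
        circ = site[18:] + "C" * 60 + site[:18]
        out = predict_targets({"m": mirna}, {"c": circ}, "circRNA")
        assert len(out) == 1
        row = out.iloc[0]
        assert row["seed_class"] == "8mer"  # miRNA starts with U -> A1 holds
        # Wrap-around coordinates: seed window crosses the junction.
        assert row["start"] > row["end"]

    def test_linear_scan_misses_junction_site(self):
        mirna = "UGAGGUAGUAGGUUGUAUAGUU"
        site = revcomp(mirna)
        seq = site[18:] + "C" * 60 + site[:18]
        out = predict_targets({"m": mirna}, {"c": seq}, "lncRNA")
        assert out.empty

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning):
            out = predict_targets({}, {}, "mRNA_3UTR")
        assert out.empty
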