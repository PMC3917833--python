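"""Seeds, extension, primer evaluation, selection criteria and pairing."""

import numpy as np
import pytest

from eukprimer.alphabet import IUPAC_SETS, reverse_complement
from eukprimer.database_io import map_to_reference
from eukprimer.entropy import ConservedBlock
from eukprimer.primer_design import (
    ExtensionConfig, PairConfig, PrimerCandidate, Seed, SelectionConfig,
    apply_selection_criteria, evaluate_primer, extend_candidate,
    reduce_degeneracy, seeds_from_blocks, select_pairs,
)
from conftest import make_db


class TestReduceDegeneracy:
    @pytest.mark.parametrize("seq,expected", [
        ("ACR", ["ACA", "ACG"]),
        ("ANT", ["AAT", "ACT", "AGT", "ATT"]),
        ("ACGT", ["ACGT"]),
    ])
    def test_expansions(self, seq, expected):
        assert reduce_degeneracy(seq) == expected

    def test_cap_refused(self):
        with pytest.raises(ValueError, match="cap"):
            reduce_degeneracy("NNNN", cap=64)  # 256 expansions


def random_record(rng, length, amb_rate=0.0):
    chars = rng.choice(list("ACGT"), size=length)
    if amb_rate:
        mask = rng.random(length) < amb_rate
        codes = [c for c in IUPAC_SETS if c not in "ACGT"]
        chars[mask] = rng.choice(codes, size=int(mask.sum()))
    return "".join(chars)


def oracle_min_mismatches(seq, probe):
    """Early-exit sliding Hamming scan with IUPAC set membership."""
    best = len(probe) + 1
    for start in range(len(seq) - len(probe) + 1):
        mm = 0
        for p, t in zip(probe, seq[start:start + len(probe)]):
            if p not in IUPAC_SETS[t]:
                mm += 1
                if mm >= best:
                    break
        best = min(best, mm)
        if best == 0:
            return 0
    return best


class TestEvaluatePrimer:
    def test_planted_in_group_absent_out_group(self):
        primer = "ACGTACGTACGTACGTAA"
        rng = np.random.default_rng(0)
        rows = []
        for i in range(10):
            background = random_record(rng, 60)
            if i < 8:
                background = background[:20] + primer + background[20 + len(primer):]
            rows.append((f"e{i}", background, "Eukaryota;P1;C;O;F;G1"))
        for i in range(5):
            rows.append((f"b{i}", random_record(rng, 60), "Bacteria;P2;C;O;F;G2"))
        db = make_db(rows)
        hits = evaluate_primer(primer, db)
        assert hits.counts["Eukaryota"][0] >= 8
        assert hits.counts["Bacteria"][0] == 0

    def test_one_substitution_needs_k1(self):
        primer = "ACGTACGTACGTACGTAA"
        mutated = "ACGTACGTACGTACGTAT"  # one 3' substitution
        db = make_db([
            ("r1", "TTTT" + mutated + "GGGG", "Eukaryota;P;C;O;F;G"),
        ])
        hits = evaluate_primer(primer, db)
        assert hits.counts["Eukaryota"][0] == 0
        assert hits.counts["Eukaryota"][1] == 1

    def test_reverse_orientation_matches_reverse_complement_site(self):
        primer = "ACTAAGAACGGCCATGCACC"
        site = reverse_complement(primer)
        db = make_db([
            ("r1", "AAAA" + site + "TTTT", "Eukaryota;P;C;O;F;G"),
        ])
        assert evaluate_primer(primer, db, "reverse").counts["Eukaryota"][0] == 1
        assert evaluate_primer(primer, db, "forward").counts["Eukaryota"][0] == 0

    def test_counts_match_hamming_oracle_with_ambiguity(self):
        rng = np.random.default_rng(21)
        rows = [
            (f"r{i}", random_record(rng, 80, amb_rate=0.03),
             f"{'Eukaryota' if i % 2 else 'Bacteria'};P;C;O;F;G{i % 4}")
            for i in range(30)
        ]
        db = make_db(rows)
        for _ in range(15):
            primer = "".join(rng.choice(list("ACGT"), size=18))
            hits = evaluate_primer(primer, db)
            for domain in ("Eukaryota", "Bacteria"):
                for k in range(3):
                    expected = sum(
                        1 for rid, seq, tax in rows
                        if tax.startswith(domain)
                        and oracle_min_mismatches(seq, primer) <= k
                    )
                    assert hits.counts.get(domain, {}).get(k, 0) == expected

    def test_counts_monotone_in_k(self, recovery_fixture):
        db, _ = recovery_fixture
        rng = np.random.default_rng(3)
        for _ in range(5):
            primer = "".join(rng.choice(list("ACGT"), size=19))
            hits = evaluate_primer(primer, db)
            for dom, counts in hits.counts.items():
                assert counts[0] <= counts[1] <= counts[2]

    def test_rank_coverage_counts_exact_match_groups(self):
        primer = "ACGTACGTACGTACGTAA"
        db = make_db([
            ("e1", primer + "AA", "Eukaryota;P1;C;O;F;G1"),
            ("e2", "A" * 20, "Eukaryota;P2;C;O;F;G2"),
        ])
        hits = evaluate_primer(primer, db)
        assert hits.rank_coverage["phylum"] == pytest.approx(0.5)
        assert hits.rank_coverage["genus"] == pytest.approx(0.5)


class TestSeedsFromBlocks:
    def test_consensus_and_reverse_complement(self):
        db = make_db([
            (f"r{i}", "GGATTCCTTA" + "ACGT", "Eukaryota;P;C;O;F;G")
            for i in range(4)
        ])
        cmap = map_to_reference(db, "r0")
        blocks = [ConservedBlock(1, 10, 1.0, 0.0)]
        seeds = seeds_from_blocks(blocks, db, cmap)
        assert seeds[0].sequence == "GGATTCCTTA"
        assert seeds[0].orientation == "forward"
        assert seeds[1].sequence == reverse_complement("GGATTCCTTA")
        assert seeds[1].orientation == "reverse"

    def test_majority_and_tie_break(self):
        # column 0: 3 G vs 2 A -> G; column 1: 2 A vs 2 C tie -> A (A<C<G<T)
        rows = [
            ("r1", "GA", "Eukaryota;P;C;O;F;G"),
            ("r2", "GA", "Eukaryota;P;C;O;F;G"),
            ("r3", "GC", "Eukaryota;P;C;O;F;G"),
            ("r4", "AC", "Eukaryota;P;C;O;F;G"),
            ("r5", "A-", "Eukaryota;P;C;O;F;G"),
        ]
        db = make_db(rows)
        cmap = map_to_reference(db, "r1")
        seeds = seeds_from_blocks([ConservedBlock(1, 2, 1.0, 0.0)], db, cmap)
        assert seeds[0].sequence == "GA"


class TestExtendCandidate:
    def test_recovers_planted_primer_and_monotone_trace(self, recovery_fixture):
        db, truth = recovery_fixture
        from eukprimer.database_io import drop_gap_only_columns, filter_by_domain
        euk = filter_by_domain(db, {"Eukaryota"})
        euk, _ = drop_gap_only_columns(euk)
        cmap = map_to_reference(euk, "REF")
        site = truth.site_records["F-101"]
        seed = Seed(site["sequence"], "forward",
                    site["ref_start"], site["ref_end"])
        trace = extend_candidate(seed, db, cmap)
        assert trace[0].sequence == site["sequence"]
        assert trace[0].hits.prokaryote_exact == 0
        # extension never increases exact in-group hits
        exact = [c.hits.target_exact for c in trace]
        assert all(a >= b for a, b in zip(exact, exact[1:]))

    def test_extension_prefers_conserved_flank(self):
        """Left flank is variable, right flank conserved: the first step
        must extend right."""
        rng = np.random.default_rng(4)
        core = "ACGTACGTACGTACGTAC"  # 18 nt seed
        rows = []
        for i in range(20):
            left = rng.choice(list("ACGT"))
            rows.append(
                (f"e{i}", f"{left}{core}GTTT", "Eukaryota;P;C;O;F;G")
            )
        db = make_db(rows)
        cmap = map_to_reference(db, "e0")
        seed = Seed(core, "forward", 2, 19)
        trace = extend_candidate(
            seed, db, cmap, ExtensionConfig(coverage_floor=0.9, max_length=19)
        )
        assert trace[-1].sequence == core + "G"
        assert trace[-1].ref_start == 2  # grew right, not left

    def test_over_long_seed_raises(self, tiny_db):
        seed = Seed("A" * 23, "forward", 1, 23)
        with pytest.raises(ValueError, match="trim"):
            extend_candidate(seed, tiny_db, map_to_reference(tiny_db, "e1"))


def make_candidate(seq, orientation="forward", start=1, prok_exact=0,
                   euk_exact=10):
    counts = {
        "Eukaryota": {0: euk_exact, 1: euk_exact, 2: euk_exact},
        "Bacteria": {0: prok_exact, 1: prok_exact, 2: prok_exact},
    }
    from eukprimer.primer_design import HitSummary
    hits = HitSummary(counts, {r: 1.0 for r in
                               ("phylum", "class", "order", "family", "genus")},
                      {"Eukaryota": 10, "Bacteria": 10})
    end = start + len(seq) - 1
    return PrimerCandidate(seq, orientation, start, end, hits)


class TestSelectionCriteria:
    def test_prokaryote_exact_match_rejected(self):
        cand = make_candidate("CAGCAGCCGCGGTAATTCC", prok_exact=2)
        kept, rejected = apply_selection_criteria([cand])
        assert not kept
        assert rejected[0].reasons == ("prokaryote exact match",)

    def test_short_exclusive_retained(self):
        cand = make_candidate("TACAAAGGGCAGGGACG")  # 17 nt, 0 prok at k<=2
        kept, rejected = apply_selection_criteria([cand])
        assert kept and kept[0].short_exclusive

    def test_short_without_exclusion_rejected(self):
        cand = make_candidate("TACAAAGGGCAGGGACG", prok_exact=0)
        hits = cand.hits.counts
        hits["Bacteria"][2] = 3  # prokaryotes appear at 2 mismatches
        kept, rejected = apply_selection_criteria([cand])
        assert not kept
        assert any("length" in r for r in rejected[0].reasons)

    def test_gc_clamp_failure_is_the_single_reason(self):
        cand = make_candidate("CAGCAGCCGCGGTAATTAA")  # AT-rich 3' end
        kept, rejected = apply_selection_criteria([cand])
        assert not kept
        assert rejected[0].reasons == ("GC clamp",)

    def test_degenerate_sequence_rejected(self):
        cand = make_candidate("CAGCAGCCGCGGTAATTCR")
        kept, rejected = apply_selection_criteria([cand])
        assert not kept
        assert rejected[0].reasons == ("degenerate sequence",)


class TestSelectPairs:
    def build_db(self, insert_len, forward, reverse):
        """Eukaryote records with F + revcomp(R) separated by insert_len."""
        rng = np.random.default_rng(6)
        rows = []
        for i in range(8):
            insert = "".join(rng.choice(list("ACGT"), size=insert_len))
            seq = "TTTT" + forward + insert + reverse_complement(reverse) + "AAAA"
            rows.append((f"e{i}", seq, "Eukaryota;P;C;O;F;G"))
        return make_db(rows)

    def pair_candidates(self, forward, reverse, insert_len):
        f = make_candidate(forward, "forward", start=5)
        r_start = 5 + len(forward) + insert_len
        r = make_candidate(reverse, "reverse", start=r_start)
        return f, r

    def test_planted_amplicon_length_and_ranking(self):
        fwd, rev = "CAGCAGCCGCGGTAATTCC", "ACTAAGAACGGCCATGCACC"
        insert = 620 - len(fwd) - len(rev)
        db = self.build_db(insert, fwd, rev)
        f, r = self.pair_candidates(fwd, rev, insert)
        pairs = select_pairs([f], [r], db)
        assert len(pairs) == 1
        assert pairs[0].amplicon_stats.mean == pytest.approx(620)
        assert pairs[0].joint_coverage_fraction == pytest.approx(1.0)
        assert pairs[0].joint_target_exact <= min(
            f.hits.target_exact, r.hits.target_exact
        )

    def test_delta_tm_cap_excludes(self):
        fwd, rev = "GCGCGCGCGCGCGCGCCGCC", "ATTATATAATTATAATATAA"
        f, r = self.pair_candidates(fwd, rev, 100)
        db = self.build_db(100, fwd, rev)
        with pytest.warns(UserWarning, match="delta_tm=1"):
            pairs = select_pairs([f], [r], db)
        assert pairs == []

    def test_hard_length_cap_excludes(self):
        fwd, rev = "CAGCAGCCGCGGTAATTCC", "ACTAAGAACGGCCATGCACC"
        insert = 900 - len(fwd) - len(rev)
        db = self.build_db(insert, fwd, rev)
        f, r = self.pair_candidates(fwd, rev, insert)
        with pytest.warns(UserWarning, match="length=1"):
            pairs = select_pairs([f], [r], db)
        assert pairs == []

    def test_wrong_orientation_order_excluded(self):
        fwd, rev = "CAGCAGCCGCGGTAATTCC", "ACTAAGAACGGCCATGCACC"
        db = self.build_db(100, fwd, rev)
        f = make_candidate(fwd, "forward", start=500)
        r = make_candidate(rev, "reverse", start=100)
        with pytest.warns(UserWarning, match="orientation=1"):
            assert select_pairs([f], [r], db) == []
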