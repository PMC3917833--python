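"""Column frequencies, Shannon entropy, and conserved-block detection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eukprimer.database_io import CoordinateMap, map_to_reference
from eukprimer.entropy import (
    BlockCriteria, EntropyProfile, column_frequencies, entropy_profile,
    find_conserved_blocks, shannon_entropy,
)
from conftest import make_db


def profile_from_values(values):
    values = np.asarray(values, dtype=float)
    cmap = CoordinateMap("ref", tuple(range(len(values))))
    return EntropyProfile("ref", values, cmap)


class TestColumnFrequencies:
    def test_ambiguity_splits_fractionally(self):
        f = column_frequencies(list("AAGR"))  # R = A or G
        assert f.effective_count == pytest.approx(4.0)
        assert f.p["A"] == pytest.approx(2.5 / 4)
        assert f.p["G"] == pytest.approx(1.5 / 4)

    def test_n_is_uniform(self):
        f = column_frequencies(["N"])
        assert all(f.p[b] == pytest.approx(0.25) for b in "ACGT")

    def test_gaps_carry_no_mass(self):
        f = column_frequencies(["A", "-", "-"])
        assert f.p["A"] == pytest.approx(1.0)
        assert f.effective_count == pytest.approx(1.0)

    def test_all_gap_column_is_undefined(self):
        f = column_frequencies(["-", "-"])
        assert not f.defined
        with pytest.raises(ValueError):
            shannon_entropy(f)

    @given(st.lists(st.sampled_from("ACGTRYN-"), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=100)
    def test_permutation_invariance(self, chars):
        f1 = column_frequencies(chars)
        f2 = column_frequencies(list(reversed(chars)))
        assert f1.effective_count == pytest.approx(f2.effective_count)
        for b in "ACGT":
            got = (f1.p[b], f2.p[b])
            assert got[0] == pytest.approx(got[1]) or all(
                math.isnan(x) for x in got
            )


class TestShannonEntropy:
    @pytest.mark.parametrize("chars,expected", [
        (list("ACGT"), 2.0),                      # uniform: maximal
        (list("AAAA"), 0.0),                      # monomorphic: none
        (list("AAGR"), 0.9544340029249649),       # hand-evaluated -sum p lg p
    ])
    def test_known_values(self, chars, expected):
        assert shannon_entropy(column_frequencies(chars)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_duplicating_majority_base_never_increases_entropy(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            chars = list(rng.choice(list("ACGT"), size=rng.integers(2, 20)))
            freqs = column_frequencies(chars)
            majority = max("ACGT", key=lambda b: freqs.p[b])
            h_before = shannon_entropy(freqs)
            h_after = shannon_entropy(column_frequencies(chars + [majority]))
            assert h_after <= h_before + 1e-12


class TestEntropyProfile:
    def test_monomorphic_and_uniform_columns(self):
        db = make_db([
            ("ref", "AA", "Eukaryota;X"),
            ("r2", "AC", "Eukaryota;X"),
            ("r3", "AG", "Eukaryota;X"),
            ("r4", "AT", "Eukaryota;X"),
        ])
        prof = entropy_profile(db, map_to_reference(db, "ref"))
        assert prof.values[0] == pytest.approx(0.0)
        assert prof.values[1] == pytest.approx(2.0)

    def test_undefined_at_reference_only_columns(self):
        # the mapped column is non-gap in the reference but gap elsewhere:
        # frequencies still defined (reference contributes); an all-gap
        # mapped column cannot arise via map_to_reference, so force one.
        prof = profile_from_values([0.1, np.nan, 0.1])
        assert np.isnan(prof.values[1])

    def test_matches_brute_force_recount(self):
        """100-record random database: profile equals independent per-column
        frequency counting and entropy evaluation."""
        rng = np.random.default_rng(7)
        n_rec, n_col = 100, 40
        chars = rng.choice(list("ACGT-"), size=(n_rec, n_col),
                           p=[0.3, 0.3, 0.2, 0.1, 0.1])
        ref = "".join(rng.choice(list("ACGT"), size=n_col))
        rows = [("ref", ref, "Eukaryota;X")] + [
            (f"r{i}", "".join(chars[i]), "Eukaryota;X") for i in range(n_rec)
        ]
        db = make_db(rows)
        cmap = map_to_reference(db, "ref")
        prof = entropy_profile(db, cmap)
        for j in range(n_col):
            col = [ref[j]] + [chars[i, j] for i in range(n_rec)]
            counts = {b: col.count(b) for b in "ACGT"}
            total = sum(counts.values())
            h = -sum(
                (c / total) * math.log2(c / total)
                for c in counts.values() if c
            )
            assert prof.values[j] == pytest.approx(h, abs=1e-12)


# ---------------------------------------------------------------------------
# conserved blocks


def oracle_blocks(values, criteria=BlockCriteria()):
    """Independent leftmost-longest enumeration of qualifying windows.

    A window [s, e] qualifies iff it starts and ends below the threshold,
    spans >= min_length positions, and >= min_fraction of its positions are
    below the threshold. Emission: smallest qualifying start, longest end.
    """
    vals = list(values)
    n = len(vals)
    L, f, t = (criteria.min_length, criteria.min_fraction_below,
               criteria.entropy_threshold)
    below = [
        (v == v) and v < t for v in vals  # NaN-safe
    ]

    def qualifies(s, e):
        if not (below[s] and below[e]):
            return False
        length = e - s + 1
        if length < L:
            return False
        return sum(below[s:e + 1]) >= f * length - 1e-12

    out = []
    pos = 0
    while pos + L <= n:
        hit = None
        for s in range(pos, n - L + 1):
            for e in range(n - 1, s + L - 2, -1):
                if qualifies(s, e):
                    hit = (s, e)
                    break
            if hit:
                break
        if not hit:
            break
        out.append((hit[0] + 1, hit[1] + 1))
        pos = hit[1] + 1
    return out


class TestFindConservedBlocks:
    def test_single_clean_block(self):
        vals = [1.5] * 5 + [0.1] * 12 + [1.5] * 5
        blocks = find_conserved_blocks(profile_from_values(vals))
        assert [(b.start, b.end) for b in blocks] == [(6, 17)]
        assert blocks[0].fraction_below == pytest.approx(1.0)

    def test_ninety_percent_rule_admits_one_interior_outlier(self):
        # 10 positions, 9 below 0.2 and 1 at 0.5: 9/10 = 90% qualifies
        vals = [1.5] * 3 + [0.1] * 5 + [0.5] + [0.1] * 4 + [1.5] * 3
        blocks = find_conserved_blocks(profile_from_values(vals))
        assert [(b.start, b.end) for b in blocks] == [(4, 13)]
        assert blocks[0].fraction_below == pytest.approx(9 / 10)

    def test_min_length_rejects_nine_positions(self):
        vals = [1.5] * 4 + [0.1] * 9 + [1.5] * 4
        assert find_conserved_blocks(profile_from_values(vals)) == []

    def test_undefined_positions_never_count_as_conserved(self):
        vals = [0.1] * 9 + [np.nan] + [0.1] * 2
        # 12 positions, 11 defined-below, but the NaN breaks 90%? 11/12 ok,
        # yet the block cannot end on / start at the NaN position.
        blocks = find_conserved_blocks(profile_from_values(vals))
        assert [(b.start, b.end) for b in blocks] == [(1, 12)]
        assert blocks[0].fraction_below == pytest.approx(11 / 12)

    def test_blocks_are_disjoint_sorted_and_qualify(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            vals = rng.uniform(0, 2, size=rng.integers(10, 120))
            vals[vals < 0.6] = 0.1  # densify conserved stretches
            blocks = find_conserved_blocks(profile_from_values(vals))
            prev_end = 0
            for b in blocks:
                assert b.start > prev_end
                assert b.length >= 10
                assert b.fraction_below >= 0.90 - 1e-12
                prev_end = b.end

    def test_matches_oracle_on_structured_profiles(self):
        """Randomized piecewise profiles vs the exhaustive oracle."""
        rng = np.random.default_rng(42)
        for _ in range(150):
            n = int(rng.integers(10, 200))
            vals = np.empty(n)
            i = 0
            while i < n:
                width = int(rng.integers(3, 25))
                level = rng.choice([0.05, 0.15, 0.3, 1.0, 1.8])
                vals[i:i + width] = level + rng.normal(0, 0.01, size=min(width, n - i))[:min(width, n - i)]
                i += width
            vals = np.clip(vals, 0, 2)
            got = [(b.start, b.end)
                   for b in find_conserved_blocks(profile_from_values(vals))]
            assert got == oracle_blocks(vals)
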