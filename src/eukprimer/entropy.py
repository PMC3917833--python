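"""Per-position Shannon entropy of an alignment and conserved-block detection.

Entropy is computed over the four nucleotides, in bits (log base 2), so a
monomorphic column scores 0 and a uniform column scores 2. Ambiguity codes
contribute fractionally to the nucleotide counts (Cornish-Bowden convention);
gaps carry no frequency mass. Columns with no nucleotide at all get a NaN
sentinel and never count as conserved.

A conserved block is a run of reference positions of length >= ``min_length``
in which at least ``min_fraction_below`` of the positions have entropy below
``entropy_threshold`` (defaults 10, 0.90, 0.2 bits). Such blocks are the seed
regions for universal primer design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alphabet import BASES, GAP, IUPAC_SETS
from .database_io import AlignedDatabase, CoordinateMap


@dataclass(frozen=True)
class NucleotideFrequencies:
    """Fractional nucleotide frequencies of one alignment column."""

    p: dict[str, float]
    effective_count: float

    @property
    def defined(self) -> bool:
        return self.effective_count > 0


@dataclass(frozen=True)
class BlockCriteria:
    min_length: int = 10
    min_fraction_below: float = 0.90
    entropy_threshold: float = 0.2

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if not 0 < self.min_fraction_below <= 1:
            raise ValueError("min_fraction_below must be in (0, 1]")
        if self.entropy_threshold < 0:
            raise ValueError("entropy_threshold must be >= 0")


@dataclass(frozen=True)
class ConservedBlock:
    """1-based inclusive reference range qualifying as conserved."""

    start: int
    end: int
    fraction_below: float
    mean_entropy: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class EntropyProfile:
    """Entropy (bits) indexed by 1-based reference position.

    ``values[i]`` is the entropy at reference position ``i + 1``; undefined
    (all-gap) positions hold NaN.
    """

    ref_id: str
    values: np.ndarray
    coordinate_map: CoordinateMap
    effective_counts: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.coordinate_map.ref_length:
            raise ValueError("profile length disagrees with coordinate map")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 2 + 1e-9):
            raise ValueError("entropy values must lie in [0, 2] bits")
        if self.effective_counts is None:
            self.effective_counts = np.full(len(self.values), np.nan)

    def __len__(self) -> int:
        return len(self.values)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("ref_position\tentropy_bits\teffective_count\n")
            for i, (h, n) in enumerate(zip(self.values, self.effective_counts), 1):
                hs = "NA" if not np.isfinite(h) else f"{h:.6g}"
                ns = "NA" if not np.isfinite(n) else f"{n:.6g}"
                fh.write(f"{i}\t{hs}\t{ns}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, ref_id: str = "") -> "EntropyProfile":
        values, counts = [], []
        with open(path) as fh:
            header = fh.readline()
            for line in fh:
                _, h, n = line.rstrip("\n").split("\t")
                values.append(float("nan") if h == "NA" else float(h))
                counts.append(float("nan") if n == "NA" else float(n))
        cmap = CoordinateMap(ref_id, tuple(range(len(values))))
        return cls(ref_id, np.array(values), cmap, np.array(counts))


def column_frequencies(column_chars) -> NucleotideFrequencies:
    """Fractional A/C/G/T frequencies of a column multiset.

    Each unambiguous base adds 1 to its own count; an ambiguity code denoting
    a set S adds 1/|S| to each member; gaps add nothing.
    """
    counts = dict.fromkeys(BASES, 0.0)
    for c in column_chars:
        if c == GAP:
            continue
        members = IUPAC_SETS.get(c)
        if members is None:
            raise ValueError(f"invalid column symbol: {c!r}")
        w = 1.0 / len(members)
        for b in members:
            counts[b] += w
    total = sum(counts.values())
    if total == 0:
        return NucleotideFrequencies(dict.fromkeys(BASES, float("nan")), 0.0)
    return NucleotideFrequencies({b: counts[b] / total for b in BASES}, total)


def shannon_entropy(freqs: NucleotideFrequencies, base: float = 2.0) -> float:
    """H = -sum p log p over the four nucleotides (0 log 0 == 0)."""
    if not freqs.defined:
        raise ValueError("entropy undefined for an all-gap column")
    h = 0.0
    for b in BASES:
        p = freqs.p[b]
        if p > 0:
            h -= p * math.log(p, base)
    return h


def entropy_profile(db: AlignedDatabase, cmap: CoordinateMap) -> EntropyProfile:
    """Entropy at every mapped column, indexed by reference position.

    All-gap mapped columns get NaN (undefined) rather than an error.
    """
    mat = db.char_matrix()
    values = np.empty(cmap.ref_length)
    counts = np.empty(cmap.ref_length)
    for i, col in enumerate(cmap.ref_positions):
        freqs = column_frequencies(mat[:, col])
        if freqs.defined:
            values[i] = shannon_entropy(freqs)
            counts[i] = freqs.effective_count
        else:
            values[i] = np.nan
            counts[i] = 0.0
    return EntropyProfile(cmap.ref_id, values, cmap, counts)


def find_conserved_blocks(
    profile: EntropyProfile, criteria: BlockCriteria = BlockCriteria()
) -> list[ConservedBlock]:
    """Disjoint, maximal conserved blocks under a leftmost-longest rule.

    A window qualifies when its length is >= ``min_length``, the fraction of
    positions with entropy < ``entropy_threshold`` is >=
    ``min_fraction_below`` (undefined positions never count as below), and
    its first and last positions are themselves below the threshold — a
    conserved block is anchored on conserved positions, so the 10% slack
    admits interior wobble but never high-entropy overhangs. Scanning left
    to right, the detector emits the window with the smallest qualifying
    start and, for that start, the largest qualifying end, then continues
    after it; emitted blocks are disjoint, sorted, and cannot be extended
    without breaking a criterion or leaving the remaining profile.
    """
    ok = np.where(np.isfinite(profile.values),
                  profile.values < criteria.entropy_threshold, False)
    n = len(ok)
    # prefix[i] = number of qualifying positions in ok[:i]
    prefix = np.concatenate([[0], np.cumsum(ok)])
    L, f = criteria.min_length, criteria.min_fraction_below

    blocks: list[ConservedBlock] = []
    pos = 0
    while pos + L <= n:
        found_start = -1
        for s in range(pos, n - L + 1):
            if not ok[s]:
                continue
            lengths = np.arange(L, n - s + 1)
            ends = s + lengths - 1
            good = ok[ends] & (
                (prefix[ends + 1] - prefix[s]) >= f * lengths - 1e-12
            )
            idx = np.flatnonzero(good)
            if idx.size:  # longest qualifying end for this start
                found_start, found_end = s, int(ends[idx[-1]])
                break
        if found_start < 0:
            break
        s, e = found_start, found_end
        window = profile.values[s : e + 1]
        frac = float(prefix[e + 1] - prefix[s]) / (e - s + 1)
        mean_h = float(np.nanmean(window)) if np.isfinite(window).any() else float("nan")
        blocks.append(ConservedBlock(s + 1, e + 1, frac, mean_h))
        pos = e + 1
    return blocks


def blocks_to_tsv(blocks: list[ConservedBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("start\tend\tlength\tfraction_below\tmean_entropy\n")
        for b in blocks:
            fh.write(
                f"{b.start}\t{b.end}\t{b.length}\t"
                f"{b.fraction_below:.6g}\t{b.mean_entropy:.6g}\n"
            )
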