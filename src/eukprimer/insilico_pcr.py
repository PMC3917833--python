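"""Mismatch-tolerant in silico PCR over unaligned (ungapped) sequences.

Primer placement is ungapped Hamming matching: a primer binds wherever the
number of mismatching positions in a window is <= k. Indels are not modeled
— primer annealing tolerates substitutions far better than bulges. Reverse
primers are matched as their reverse complement on the sense strand; SSU
databases are orientation-normalized, so only the sense strand is searched.

A template base carrying an ambiguity code matches a primer base iff the
primer base is a member of the code's set.

An amplicon spans the 5' end of the forward footprint through the 5' end of
the reverse primer (the last base of its sense-strand footprint), inclusive,
so its length includes both primer footprints.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alphabet import IUPAC_BITS, is_unambiguous, reverse_complement
from .database_io import RANK_INDEX, RANKS, AlignedDatabase

_BIT_LUT = np.zeros(128, dtype=np.uint8)
for _c, _b in IUPAC_BITS.items():
    _BIT_LUT[ord(_c)] = _b


def encode(seq: str) -> np.ndarray:
    """4-bit mask encoding of a nucleotide string (gap -> 0 matches nothing)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _BIT_LUT[arr]


def mismatch_counts(seq: str | np.ndarray, primer: str) -> np.ndarray:
    """Mismatches of *primer* against every window of *seq* (sense strand).

    Entry ``i`` is the Hamming mismatch count of the primer laid on
    ``seq[i : i + len(primer)]``. Empty if the primer is longer than seq.
    """
    if not is_unambiguous(primer):
        raise ValueError(f"primer must be unambiguous: {primer!r}")
    tpl = seq if isinstance(seq, np.ndarray) else encode(seq)
    p = encode(primer)
    m = len(p)
    if m > len(tpl):
        return np.zeros(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(tpl, m)
    return ((windows & p) == 0).sum(axis=1)


def find_primer_sites(
    seq: str | np.ndarray,
    primer: str,
    orientation: str = "forward",
    k: int = 0,
) -> list[tuple[int, int]]:
    """All placements of a primer on the sense strand at <= k mismatches.

    Returns (position, mismatches) pairs where position is the 1-based start
    of the footprint on the ungapped sense sequence. Reverse primers are
    searched as their reverse complement.
    """
    if orientation not in ("forward", "reverse"):
        raise ValueError(f"orientation must be forward|reverse: {orientation!r}")
    probe = primer if orientation == "forward" else reverse_complement(primer)
    counts = mismatch_counts(seq, probe)
    hits = np.flatnonzero(counts <= k)
    return [(int(i) + 1, int(counts[i])) for i in hits]


@dataclass(frozen=True)
class Amplicon:
    """A virtual PCR product on one record's ungapped sense sequence."""

    record_id: str
    start: int  # 1-based inclusive, 5' end of forward footprint
    end: int    # 1-based inclusive, 5' end of reverse primer on sense strand
    mismatches_f: int
    mismatches_r: int
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def amplify(
    seq: str,
    forward: str,
    reverse: str,
    k: int = 0,
    record_id: str = "",
    policy: str = "outermost",
) -> list[Amplicon]:
    """Virtual amplification of one sense-strand template.

    Compatible site pairs have the reverse footprint strictly downstream of
    the forward footprint. ``policy`` selects which compatible pair(s) to
    report: ``"outermost"`` (longest product, the default), ``"innermost"``
    (shortest), or ``"all"``.
    """
    if policy not in ("outermost", "innermost", "all"):
        raise ValueError(f"unknown site-pairing policy {policy!r}")
    tpl = encode(seq)
    f_sites = find_primer_sites(tpl, forward, "forward", k)
    r_sites = find_primer_sites(tpl, reverse, "reverse", k)
    len_f, len_r = len(forward), len(reverse)

    pairs = [
        (fs, fm, rs, rm)
        for fs, fm in f_sites
        for rs, rm in r_sites
        if rs >= fs + len_f  # reverse footprint downstream of forward's
    ]
    if not pairs:
        return []
    if policy == "outermost":
        pairs = [max(pairs, key=lambda p: p[2] + len_r - p[0])]
    elif policy == "innermost":
        pairs = [min(pairs, key=lambda p: p[2] + len_r - p[0])]
    out = []
    for fs, fm, rs, rm in pairs:
        end = rs + len_r - 1
        out.append(
            Amplicon(record_id, fs, end, fm, rm, seq[fs - 1 : end])
        )
    return out


@dataclass(frozen=True)
class CoverageReport:
    """Covered/uncovered groups at one taxonomic rank for one primer pair."""

    rank: str
    per_group: dict[str, bool]
    skipped_records: int
    k: int

    @property
    def groups_total(self) -> int:
        return len(self.per_group)

    @property
    def groups_covered(self) -> int:
        return sum(self.per_group.values())

    @property
    def excluded_groups(self) -> list[str]:
        return sorted(g for g, cov in self.per_group.items() if not cov)

    @property
    def coverage_fraction(self) -> float:
        return self.groups_covered / self.groups_total if self.per_group else 0.0

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("rank\tgroup\tcovered\n")
            for g in sorted(self.per_group):
                fh.write(f"{self.rank}\t{g}\t{int(self.per_group[g])}\n")


def coverage_by_rank(
    db: AlignedDatabase,
    forward: str,
    reverse: str,
    rank: str = "phylum",
    k: int = 0,
    policy: str = "outermost",
) -> CoverageReport:
    """Which groups at *rank* contain >= 1 record the pair amplifies at <= k.

    A group is considered covered iff at least one of its records yields an
    amplicon; with the default k=0 this is the perfect-match semantics used
    for 'covered' claims. Records lacking a label at the rank are skipped
    and counted.
    """
    if rank not in RANK_INDEX:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    per_group: dict[str, bool] = {}
    skipped = 0
    for rec in db.records:
        label = rec.rank_label(rank)
        if label is None:
            skipped += 1
            continue
        amplified = bool(
            amplify(rec.ungapped, forward, reverse, k, rec.id, policy)
        )
        per_group[label] = per_group.get(label, False) or amplified
    return CoverageReport(rank, per_group, skipped, k)


@dataclass(frozen=True)
class LengthDistribution:
    n: int
    mean: float
    min: int
    max: int
    window: tuple[int, int]
    fraction_in_window: float


def amplicon_length_distribution(
    amplicons: list[Amplicon], window: tuple[int, int] = (530, 700)
) -> LengthDistribution:
    """Mean/min/max amplicon length and the fraction inside [lo, hi]."""
    if not amplicons:
        raise ValueError("no amplicons to summarize")
    lengths = np.array([a.length for a in amplicons])
    lo, hi = window
    return LengthDistribution(
        n=len(lengths),
        mean=float(lengths.mean()),
        min=int(lengths.min()),
        max=int(lengths.max()),
        window=window,
        fraction_in_window=float(((lengths >= lo) & (lengths <= hi)).mean()),
    )


def write_amplicons_fasta(amplicons: list[Amplicon], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in amplicons:
            fh.write(
                f">{a.record_id}:{a.start}-{a.end} "
                f"mm_f={a.mismatches_f} mm_r={a.mismatches_r}\n{a.sequence}\n"
            )


def write_amplicons_bed(amplicons: list[Amplicon], path: str | Path) -> None:
    """BED-like TSV: record, 0-based half-open interval, name, mismatches."""
    with open(path, "w") as fh:
        for a in amplicons:
            fh.write(
                f"{a.record_id}\t{a.start - 1}\t{a.end}\t"
                f"amplicon\t{a.mismatches_f}\t{a.mismatches_r}\n"
            )
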