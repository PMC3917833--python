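"""Candidate primer generation from conserved blocks, evaluation and pairing.

The design loop mirrors how universal SSU primers are found in practice:

1. a conserved block's majority consensus becomes a seed, in both the
   forward orientation and (reverse-complemented) as a reverse primer seed;
2. the seed is extended one nucleotide at a time into its flanks, each step
   choosing the flank/base that keeps the most exact in-group (eukaryote)
   matches, and every step is re-scored against the whole database;
3. a fixed list of selection criteria prunes candidates (no prokaryote
   exact matches, no degeneracy, 18-22 nt with a short-primer exception for
   candidates that already exclude prokaryotes, 3' GC clamp, clean
   hairpin/self-dimer screens);
4. surviving forward x reverse combinations are paired under amplicon-length
   and delta-Tm constraints and ranked by joint eukaryote coverage.

"Hits" count matching sequence records, not collapsed taxa.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alphabet import BASES, IUPAC_SETS, is_unambiguous, reverse_complement
from .database_io import RANKS, AlignedDatabase, CoordinateMap
from .entropy import ConservedBlock, column_frequencies
from .insilico_pcr import amplify, encode, mismatch_counts
from .thermo import ThermoProfile, thermo_profile

log = logging.getLogger(__name__)

PROKARYOTE_DOMAINS = ("Bacteria", "Archaea")
COVERAGE_RANKS = tuple(r for r in RANKS if r != "domain")


# ---------------------------------------------------------------------------
# degeneracy

def reduce_degeneracy(degenerate_seq: str, cap: int = 64) -> list[str]:
    """Cartesian expansion of an IUPAC-degenerate sequence.

    Refuses expansions larger than *cap* (the point of this pipeline is
    non-degenerate primers; huge expansions signal a mistake).
    """
    sets = []
    count = 1
    for c in degenerate_seq:
        members = IUPAC_SETS.get(c)
        if members is None:
            raise ValueError(f"invalid IUPAC symbol {c!r} in {degenerate_seq!r}")
        choices = sorted(members)
        count *= len(choices)
        if count > cap:
            raise ValueError(
                f"degeneracy of {degenerate_seq!r} exceeds cap {cap}"
            )
        sets.append(choices)
    return ["".join(p) for p in itertools.product(*sets)]


# ---------------------------------------------------------------------------
# evaluation

@dataclass(frozen=True)
class HitSummary:
    """Match counts per domain at 0/1/2 mismatches plus rank coverage.

    ``counts[domain][k]`` is the number of records of *domain* carrying at
    least one primer site at <= k mismatches (non-decreasing in k).
    ``rank_coverage[rank]`` is the fraction of in-group taxa at that rank
    with >= 1 exact-match (k=0) record.
    """

    counts: dict[str, dict[int, int]]
    rank_coverage: dict[str, float]
    domain_totals: dict[str, int]
    target_domain: str = "Eukaryota"

    def exact(self, domain: str) -> int:
        return self.counts.get(domain, {}).get(0, 0)

    @property
    def target_exact(self) -> int:
        return self.exact(self.target_domain)

    @property
    def prokaryote_exact(self) -> int:
        return sum(self.exact(d) for d in PROKARYOTE_DOMAINS)

    def prokaryote_at(self, k: int) -> int:
        return sum(self.counts.get(d, {}).get(k, 0) for d in PROKARYOTE_DOMAINS)

    @property
    def target_coverage_fraction(self) -> float:
        total = self.domain_totals.get(self.target_domain, 0)
        return self.target_exact / total if total else 0.0


def evaluate_primer(
    primer: str,
    db: AlignedDatabase,
    orientation: str = "forward",
    k_max: int = 2,
    target_domain: str = "Eukaryota",
) -> HitSummary:
    """Score one unambiguous primer against every record of the database.

    Forward primers are matched as-is on the sense strand; reverse primers
    as their reverse complement. A record is a hit at level k if the primer
    occurs anywhere in its ungapped sequence with <= k mismatches.
    """
    if not is_unambiguous(primer):
        raise ValueError(
            f"evaluate_primer requires an unambiguous primer, got {primer!r}; "
            "use reduce_degeneracy first"
        )
    probe = primer if orientation == "forward" else reverse_complement(primer)
    counts: dict[str, dict[int, int]] = {}
    domain_totals: dict[str, int] = {}
    rank_groups: dict[str, set[str]] = {r: set() for r in COVERAGE_RANKS}
    rank_covered: dict[str, set[str]] = {r: set() for r in COVERAGE_RANKS}
    for rec in db.records:
        dom = rec.domain
        domain_totals[dom] = domain_totals.get(dom, 0) + 1
        mm = mismatch_counts(rec.ungapped, probe)
        best = int(mm.min()) if mm.size else k_max + 1
        dom_counts = counts.setdefault(dom, {k: 0 for k in range(k_max + 1)})
        for k in range(k_max + 1):
            if best <= k:
                dom_counts[k] += 1
        if dom == target_domain:
            for rank in COVERAGE_RANKS:
                label = rec.rank_label(rank)
                if label is None:
                    continue
                rank_groups[rank].add(label)
                if best == 0:
                    rank_covered[rank].add(label)
    rank_coverage = {
        r: (len(rank_covered[r]) / len(rank_groups[r]) if rank_groups[r] else 0.0)
        for r in COVERAGE_RANKS
    }
    return HitSummary(counts, rank_coverage, domain_totals, target_domain)


# ---------------------------------------------------------------------------
# seeds and extension

@dataclass(frozen=True)
class Seed:
    """Block consensus in one orientation, anchored on reference coordinates."""

    sequence: str        # 5'->3' as synthesized
    orientation: str     # forward | reverse
    ref_start: int       # 1-based sense-strand footprint, inclusive
    ref_end: int

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start + 1


@dataclass(frozen=True)
class PrimerCandidate:
    """A primer with its footprint, physical profile and database hits.

    Ids follow the field convention "<F|R>-<1-based reference position of
    the 5' terminus>": for a forward primer that is the footprint start, for
    a reverse primer the footprint end.
    """

    sequence: str
    orientation: str
    ref_start: int
    ref_end: int
    hits: HitSummary
    thermo: ThermoProfile | None = None
    short_exclusive: bool = False

    @property
    def ref_position_5prime(self) -> int:
        return self.ref_start if self.orientation == "forward" else self.ref_end

    @property
    def id(self) -> str:
        tag = "F" if self.orientation == "forward" else "R"
        return f"{tag}-{self.ref_position_5prime}"

    @property
    def length(self) -> int:
        return len(self.sequence)


def consensus_sequence(db: AlignedDatabase, columns) -> str:
    """Majority-consensus base per column (fractional counts, ties A<C<G<T)."""
    mat = db.char_matrix()
    out = []
    for col in columns:
        freqs = column_frequencies(mat[:, col])
        if not freqs.defined:
            out.append("A")  # no information at all; fixed arbitrary base
            continue
        out.append(max(BASES, key=lambda b: (freqs.p[b], )))
    return "".join(out)


def _majority(freqs) -> str:
    # ties broken by fixed base order A < C < G < T (max keeps the first
    # maximal element only with explicit handling)
    best, best_p = "A", -1.0
    for b in BASES:
        if freqs.p[b] > best_p + 1e-12:
            best, best_p = b, freqs.p[b]
    return best


def seeds_from_blocks(
    blocks: list[ConservedBlock],
    db: AlignedDatabase,
    cmap: CoordinateMap,
) -> list[Seed]:
    """Forward and reverse seeds from each conserved block's consensus."""
    mat = db.char_matrix()
    seeds: list[Seed] = []
    for block in blocks:
        cols = cmap.columns_of_range(block.start, block.end)
        sense = "".join(
            _majority(column_frequencies(mat[:, c])) for c in cols
        )
        seeds.append(Seed(sense, "forward", block.start, block.end))
        seeds.append(
            Seed(reverse_complement(sense), "reverse", block.start, block.end)
        )
    return seeds


@dataclass(frozen=True)
class ExtensionConfig:
    min_length: int = 18
    max_length: int = 22
    #: stop extending once the best step's exact in-group coverage falls
    #: below this fraction of in-group records
    coverage_floor: float = 0.8
    k_max: int = 2
    target_domain: str = "Eukaryota"


def extend_candidate(
    seed: Seed,
    db: AlignedDatabase,
    cmap: CoordinateMap,
    config: ExtensionConfig = ExtensionConfig(),
) -> list[PrimerCandidate]:
    """Greedy bidirectional extension of a seed, returning the trace.

    At each step both flanking columns are tried with all four bases; the
    extension keeping the most exact in-group hits is taken (ties: left
    flank first, bases in A<C<G<T order). Extension stops at ``max_length``,
    at the reference bounds, or when the best step's in-group coverage drops
    below ``coverage_floor``. The trace contains every intermediate of
    length >= ``min_length`` plus shorter intermediates that already have
    zero prokaryote exact hits (flagged short-exclusive).
    """
    if seed.length > config.max_length:
        raise ValueError(
            f"seed of length {seed.length} exceeds max_length "
            f"{config.max_length}; trim the seed"
        )
    n_target = sum(
        1 for r in db.records if r.domain == config.target_domain
    )
    floor_hits = config.coverage_floor * n_target

    def sense_of(primer: str) -> str:
        return primer if seed.orientation == "forward" else reverse_complement(primer)

    def make_candidate(primer: str, s: int, e: int) -> PrimerCandidate:
        hits = evaluate_primer(
            primer, db, seed.orientation, config.k_max, config.target_domain
        )
        short = len(primer) < config.min_length
        return PrimerCandidate(
            primer, seed.orientation, s, e, hits,
            short_exclusive=short and hits.prokaryote_exact == 0,
        )

    trace: list[PrimerCandidate] = []

    def record(cand: PrimerCandidate) -> None:
        if cand.length >= config.min_length or cand.hits.prokaryote_exact == 0:
            trace.append(cand)

    sense = sense_of(seed.sequence)
    s, e = seed.ref_start, seed.ref_end
    current = make_candidate(seed.sequence, s, e)
    record(current)
    while current.length < config.max_length:
        options: list[tuple[int, str, str, int, int]] = []
        for flank in ("left", "right"):
            if flank == "left" and s <= 1:
                continue
            if flank == "right" and e >= cmap.ref_length:
                continue
            for base in BASES:
                if flank == "left":
                    new_sense = base + sense
                    ns, ne = s - 1, e
                else:
                    new_sense = sense + base
                    ns, ne = s, e + 1
                primer = (
                    new_sense if seed.orientation == "forward"
                    else reverse_complement(new_sense)
                )
                probe = new_sense  # matching always happens on sense strand
                exact = sum(
                    1
                    for r in db.records
                    if r.domain == config.target_domain
                    and (lambda m: m.size and m.min() == 0)(
                        mismatch_counts(r.ungapped, probe)
                    )
                )
                options.append((exact, primer, new_sense, ns, ne))
        if not options:
            break
        best = max(options, key=lambda o: o[0])  # ties: first in scan order
        if best[0] < floor_hits:
            break
        _, primer, sense, s, e = best
        current = make_candidate(primer, s, e)
        record(current)
    return trace


# ---------------------------------------------------------------------------
# selection criteria

@dataclass(frozen=True)
class SelectionConfig:
    max_prokaryote_exact: int = 0
    min_length: int = 18
    max_length: int = 22
    gc_clamp_rule: str = "last3"
    allow_short_exclusive: bool = True
    k_max: int = 2


@dataclass(frozen=True)
class Rejection:
    candidate_id: str
    sequence: str
    reasons: tuple[str, ...]


def apply_selection_criteria(
    candidates: list[PrimerCandidate],
    config: SelectionConfig = SelectionConfig(),
) -> tuple[list[PrimerCandidate], list[Rejection]]:
    """Prune candidates by the fixed criteria; log every violated criterion.

    Kept candidates get their :class:`ThermoProfile` attached and are ranked
    by exact in-group hits, then rank coverage, then id.
    """
    from dataclasses import replace
    from .thermo import gc_clamp

    kept: list[PrimerCandidate] = []
    rejections: list[Rejection] = []
    seen: set[tuple[str, str, int]] = set()
    for cand in candidates:
        key = (cand.sequence, cand.orientation, cand.ref_start)
        if key in seen:
            continue
        seen.add(key)
        reasons: list[str] = []
        if not is_unambiguous(cand.sequence):
            reasons.append("degenerate sequence")
            rejections.append(Rejection(cand.id, cand.sequence, tuple(reasons)))
            continue
        if cand.hits.prokaryote_exact > config.max_prokaryote_exact:
            reasons.append("prokaryote exact match")
        short_ok = (
            config.allow_short_exclusive
            and all(
                cand.hits.prokaryote_at(k) == 0
                for k in range(config.k_max + 1)
            )
        )
        if cand.length > config.max_length:
            reasons.append(f"length > {config.max_length}")
        elif cand.length < config.min_length and not short_ok:
            reasons.append(
                f"length < {config.min_length} without prokaryote exclusion"
            )
        profile = thermo_profile(cand.sequence)
        clamp = (
            profile.gc_clamp_3of3
            if config.gc_clamp_rule == "last3"
            else profile.gc_clamp_5prime_rule
        )
        if not clamp:
            reasons.append("GC clamp")
        if profile.hairpin_flag:
            reasons.append("hairpin")
        if profile.self_dimer_flag:
            reasons.append("self-dimer")
        if reasons:
            rejections.append(Rejection(cand.id, cand.sequence, tuple(reasons)))
            log.info("rejected %s: %s", cand.id, "; ".join(reasons))
            continue
        kept.append(
            replace(
                cand,
                thermo=profile,
                short_exclusive=cand.length < config.min_length,
            )
        )
    kept.sort(
        key=lambda c: (
            -c.hits.target_exact,
            -float(np.mean(list(c.hits.rank_coverage.values()) or [0.0])),
            c.id,
        )
    )
    return kept, rejections


# ---------------------------------------------------------------------------
# pairing

@dataclass(frozen=True)
class AmpliconStats:
    n: int
    mean: float
    min: int
    max: int
    q10: float
    q90: float


@dataclass(frozen=True)
class PrimerPair:
    forward: PrimerCandidate
    reverse: PrimerCandidate
    delta_tm: float
    amplicon_stats: AmpliconStats | None
    joint_target_exact: int          # records amplified at k=0
    joint_coverage_fraction: float   # of in-group records
    prokaryote_joint_hits: dict[int, int]

    @property
    def id(self) -> str:
        return f"{self.forward.id}/{self.reverse.id}"


@dataclass(frozen=True)
class PairConfig:
    delta_tm_max: float = 5.0
    optimal_length: tuple[int, int] = (500, 650)
    hard_max_length: int = 800
    tag_adapter_allowance: int = 0
    k_max: int = 2
    target_domain: str = "Eukaryota"
    site_policy: str = "outermost"


def select_pairs(
    forwards: list[PrimerCandidate],
    reverses: list[PrimerCandidate],
    db: AlignedDatabase,
    config: PairConfig = PairConfig(),
) -> list[PrimerPair]:
    """Pair and rank surviving forward/reverse candidates.

    Only combinations with the reverse footprint downstream of the forward
    footprint on the reference are considered. Pairs are kept when delta-Tm
    is below the cap and the mean predicted amplicon fits under the hard
    length cap (minus the tag/adapter allowance); ranking is by joint
    in-group coverage, then closeness of the mean amplicon length to the
    optimal window's midpoint.
    """
    targets = [r for r in db.records if r.domain == config.target_domain]
    prok = [r for r in db.records if r.domain in PROKARYOTE_DOMAINS]
    n_target = len(targets)
    hard_cap = config.hard_max_length - config.tag_adapter_allowance
    midpoint = sum(config.optimal_length) / 2.0

    constraint_counts = {"orientation": 0, "delta_tm": 0, "length": 0, "no_amplicon": 0}
    pairs: list[PrimerPair] = []
    for f, r in itertools.product(forwards, reverses):
        if r.ref_start <= f.ref_end:
            constraint_counts["orientation"] += 1
            continue
        f_thermo = f.thermo or thermo_profile(f.sequence)
        r_thermo = r.thermo or thermo_profile(r.sequence)
        delta_tm = abs(f_thermo.tm_celsius - r_thermo.tm_celsius)
        if delta_tm >= config.delta_tm_max:
            constraint_counts["delta_tm"] += 1
            continue
        lengths = []
        for rec in targets:
            amps = amplify(
                rec.ungapped, f.sequence, r.sequence, 0, rec.id,
                config.site_policy,
            )
            if amps:
                lengths.append(amps[0].length)
        if not lengths:
            constraint_counts["no_amplicon"] += 1
            continue
        arr = np.array(lengths)
        stats = AmpliconStats(
            n=len(arr), mean=float(arr.mean()), min=int(arr.min()),
            max=int(arr.max()),
            q10=float(np.quantile(arr, 0.1)), q90=float(np.quantile(arr, 0.9)),
        )
        if stats.mean >= hard_cap:
            constraint_counts["length"] += 1
            continue
        prok_joint = {
            k: sum(
                1 for rec in prok
                if amplify(rec.ungapped, f.sequence, r.sequence, k, rec.id,
                           config.site_policy)
            )
            for k in range(config.k_max + 1)
        }
        pairs.append(
            PrimerPair(
                forward=f, reverse=r, delta_tm=delta_tm,
                amplicon_stats=stats,
                joint_target_exact=stats.n,
                joint_coverage_fraction=stats.n / n_target if n_target else 0.0,
                prokaryote_joint_hits=prok_joint,
            )
        )
    if not pairs:
        warnings.warn(
            "no primer pair survived; binding constraints: "
            + ", ".join(f"{k}={v}" for k, v in constraint_counts.items())
        )
    pairs.sort(
        key=lambda p: (
            -p.joint_coverage_fraction,
            abs(p.amplicon_stats.mean - midpoint),
            p.id,
        )
    )
    return pairs


# ---------------------------------------------------------------------------
# I/O helpers

def read_primers_tsv(path: str | Path) -> list[tuple[str, str, str]]:
    """Read (name, sequence, orientation) rows; '#' comments skipped."""
    rows: list[tuple[str, str, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].lower() in ("name", "id"):
                continue
            name, seq, orientation = parts[0], parts[1].upper(), parts[2]
            rows.append((name, seq, orientation))
    return rows


def _fmt_hits(h: HitSummary, domain: str, k_max: int = 2) -> str:
    c = h.counts.get(domain, {})
    extra = "/".join(str(c.get(k, 0)) for k in range(1, k_max + 1))
    return f"{c.get(0, 0)} ({extra})" if k_max >= 1 else str(c.get(0, 0))


def candidates_to_tsv(
    candidates: list[PrimerCandidate], path: str | Path
) -> None:
    """Candidate table in the conventional primer-survey layout."""
    with open(path, "w") as fh:
        fh.write("Id\tSequence\tHits\tEukaryotes\tBacteria\tArchaea\tTm\t%GC\n")
        for c in candidates:
            thermo = c.thermo or thermo_profile(c.sequence)
            total = sum(c.hits.exact(d) for d in c.hits.counts)
            fh.write(
                f"{c.id}\t{c.sequence}\t{total}\t{c.hits.target_exact}\t"
                f"{_fmt_hits(c.hits, 'Bacteria')}\t{_fmt_hits(c.hits, 'Archaea')}\t"
                f"{thermo.tm_celsius:.1f}\t{thermo.gc_percent:.1f}\n"
            )


def pairs_to_tsv(pairs: list[PrimerPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "Pair\tForward\tReverse\tDeltaTm\tMeanLength\tMinLength\t"
            "MaxLength\tJointCoverage\tProk_k0\tProk_k1\tProk_k2\n"
        )
        for p in pairs:
            st = p.amplicon_stats
            fh.write(
                f"{p.id}\t{p.forward.sequence}\t{p.reverse.sequence}\t"
                f"{p.delta_tm:.2f}\t{st.mean:.1f}\t{st.min}\t{st.max}\t"
                f"{p.joint_coverage_fraction:.4f}\t"
                f"{p.prokaryote_joint_hits.get(0, 0)}\t"
                f"{p.prokaryote_joint_hits.get(1, 0)}\t"
                f"{p.prokaryote_joint_hits.get(2, 0)}\n"
            )
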