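"""Deterministic synthetic aligned databases with known ground truth.

The generator emulates what the design pipeline consumes from a curated SSU
rRNA database: an alignment of taxonomically labeled sequences with designed
per-column entropy structure (conserved blocks and variable regions),
planted primer sites that are present in a target group and carried with a
fixed number of substitutions by an out-group, gap-only columns, and
hierarchical taxonomy down to genus. Columns are sampled independently;
real phylogenetic covariance between columns is deliberately not modeled.

Entropy targets are realized by a two-parameter column distribution: one
majority base with probability p and the other three bases at (1-p)/3 each,
where p is solved numerically so the analytic entropy equals the target.
Every draw flows from a single integer seed, so equal specs give
byte-identical databases.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .alphabet import BASES, GAP, reverse_complement
from .database_io import AlignedDatabase, CoordinateMap, Record
from .entropy import BlockCriteria, ConservedBlock, EntropyProfile, find_conserved_blocks

REFERENCE_TAXONOMY = (
    "Eukaryota", "Ascomycota", "Saccharomycetes", "Saccharomycetales",
    "Saccharomycetaceae", "Saccharomyces",
)


@dataclass(frozen=True)
class Segment:
    """A stretch of reference positions with a common entropy target.

    ``genus_structured`` draws one consensus per genus (records of a genus
    are identical over the segment) instead of independent per-record
    draws; per-column entropy then holds across genera in expectation.
    """

    name: str
    length: int
    entropy: float  # target per-column entropy, bits in [0, 2]
    genus_structured: bool = False

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"segment {self.name}: length must be >= 1")
        if not 0.0 <= self.entropy <= 2.0:
            raise ValueError(f"segment {self.name}: entropy outside [0, 2]")


@dataclass(frozen=True)
class TaxonGroup:
    """One genus-level group of records sharing a full lineage."""

    domain: str
    phylum: str
    klass: str
    order: str
    family: str
    genus: str
    n_records: int

    @property
    def taxonomy(self) -> tuple[str, ...]:
        return (
            self.domain, self.phylum, self.klass, self.order,
            self.family, self.genus,
        )


@dataclass(frozen=True)
class PlantedSite:
    """A primer site written into the alignment with known presence.

    ``sequence`` is the primer 5'->3'; the sense-strand characters placed in
    the alignment are the sequence itself (forward) or its reverse
    complement (reverse). In-group records carry the site verbatim with
    probability-free exactness (a fixed fraction of records, chosen by the
    seeded RNG); every out-group record carries a copy with exactly
    ``out_group_mismatches`` substitutions at evenly spaced positions.
    """

    sequence: str
    orientation: str  # forward | reverse
    ref_start: int    # 1-based reference position of the sense footprint
    in_group_domain: str = "Eukaryota"
    presence: float = 1.0
    out_group_mismatches: int = 3

    @property
    def ref_end(self) -> int:
        return self.ref_start + len(self.sequence) - 1

    @property
    def sense_sequence(self) -> str:
        if self.orientation == "forward":
            return self.sequence
        return reverse_complement(self.sequence)

    @property
    def primer_id(self) -> str:
        tag = "F" if self.orientation == "forward" else "R"
        pos = self.ref_start if self.orientation == "forward" else self.ref_end
        return f"{tag}-{pos}"


@dataclass
class FixtureSpec:
    segments: list[Segment]
    groups: list[TaxonGroup]
    planted_sites: list[PlantedSite] = field(default_factory=list)
    gap_columns: list[int] = field(default_factory=list)  # final-alignment indices
    seed: int = 0
    reference_id: str = "REF"
    include_reference: bool = True

    @property
    def ref_length(self) -> int:
        return sum(s.length for s in self.segments)

    def validate(self) -> None:
        n = self.ref_length
        occupied: set[int] = set()
        for site in self.planted_sites:
            if not 0.0 <= site.presence <= 1.0:
                raise ValueError(f"site {site.primer_id}: presence outside [0,1]")
            if site.out_group_mismatches < 0:
                raise ValueError(f"site {site.primer_id}: negative mismatches")
            if site.out_group_mismatches > len(site.sequence):
                raise ValueError(
                    f"site {site.primer_id}: more mismatches than bases"
                )
            if site.ref_start < 1 or site.ref_end > n:
                raise ValueError(
                    f"site {site.primer_id} outside reference 1..{n}"
                )
            span = set(range(site.ref_start, site.ref_end + 1))
            if span & occupied:
                raise ValueError(f"site {site.primer_id} overlaps another site")
            occupied |= span
        total_cols = n + len(self.gap_columns)
        for g in self.gap_columns:
            if not 0 <= g < total_cols:
                raise ValueError(f"gap column {g} outside 0..{total_cols - 1}")
        if len(set(self.gap_columns)) != len(self.gap_columns):
            raise ValueError("duplicate gap column positions")

    # --- JSON round trip ---------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "FixtureSpec":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            segments=[Segment(**s) for s in raw["segments"]],
            groups=[TaxonGroup(**g) for g in raw["groups"]],
            planted_sites=[PlantedSite(**p) for p in raw["planted_sites"]],
            gap_columns=list(raw.get("gap_columns", [])),
            seed=raw.get("seed", 0),
            reference_id=raw.get("reference_id", "REF"),
            include_reference=raw.get("include_reference", True),
        )


@dataclass
class GroundTruth:
    """What the generator planted, re-verifiable by scanning the database."""

    ref_length: int
    expected_entropy: np.ndarray       # analytic per-reference-position, in-group
    expected_blocks: list[ConservedBlock]
    site_records: dict[str, dict]      # primer_id -> site details + record ids
    gap_columns: list[int]
    genus_consensus: dict[str, dict[str, str]]  # segment -> genus -> sequence
    expected_amplicon_length: int | None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "ref_length": self.ref_length,
            "expected_blocks": [
                [b.start, b.end] for b in self.expected_blocks
            ],
            "site_records": self.site_records,
            "gap_columns": self.gap_columns,
            "genus_consensus": self.genus_consensus,
            "expected_amplicon_length": self.expected_amplicon_length,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _entropy_of_p(p: float) -> float:
    """Entropy (bits) of the majority-p column distribution."""
    h = 0.0
    if p > 0:
        h -= p * math.log2(p)
    q = (1.0 - p) / 3.0
    if q > 0:
        h -= 3 * q * math.log2(q)
    return h


def majority_probability(target_entropy: float) -> float:
    """Majority-base probability whose column entropy equals the target."""
    if target_entropy <= 0:
        return 1.0
    if target_entropy >= 2.0:
        return 0.25
    return float(
        brentq(lambda p: _entropy_of_p(p) - target_entropy, 0.25, 1.0 - 1e-12)
    )


def _mixture_entropy(probs: np.ndarray) -> float:
    nz = probs[probs > 0]
    return float(-(nz * np.log2(nz)).sum())


def _column_models(spec: FixtureSpec, rng: np.random.Generator) -> list[dict]:
    """Per-reference-column sampling model, deterministic given the seed.

    Each model has the segment, the majority base, and the base probabilities.
    Consumes the RNG first, so record sampling downstream sees a fixed state.
    """
    models = []
    for seg in spec.segments:
        p = majority_probability(seg.entropy)
        for _ in range(seg.length):
            major = BASES[rng.integers(0, 4)]
            probs = np.full(4, (1.0 - p) / 3.0)
            probs[BASES.index(major)] = p
            models.append({"segment": seg, "major": major, "probs": probs})
    return models


def _mutated_copy(seq: str, n_mut: int) -> str:
    """Exactly n_mut substitutions at evenly spaced positions (deterministic)."""
    if n_mut == 0:
        return seq
    chars = list(seq)
    L = len(chars)
    positions = sorted({int((i + 0.5) * L / n_mut) for i in range(n_mut)})
    # set collisions can only shrink the set; pad from unused positions
    extra = (i for i in range(L) if i not in positions)
    while len(positions) < n_mut:
        positions.append(next(extra))
    for i in sorted(positions[:n_mut]):
        chars[i] = BASES[(BASES.index(chars[i]) + 1) % 4]
    return "".join(chars)


def generate(spec: FixtureSpec) -> tuple[AlignedDatabase, GroundTruth]:
    """Build the aligned database and its ground truth from a spec."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    models = _column_models(spec, rng)
    n_ref = spec.ref_length

    # record roster, in deterministic order
    roster: list[tuple[str, tuple[str, ...]]] = []
    for g in spec.groups:
        for i in range(g.n_records):
            roster.append((f"{g.genus}_{i + 1}", g.taxonomy))
    n_rec = len(roster)
    genera = [tax[5] for _, tax in roster]
    unique_genera = sorted(set(genera))

    mat = np.empty((n_rec, n_ref), dtype="U1")
    genus_consensus: dict[str, dict[str, str]] = {}
    col = 0
    for seg in spec.segments:
        seg_cols = range(col, col + seg.length)
        if seg.genus_structured:
            cons = {g: [] for g in unique_genera}
            for c in seg_cols:
                probs = models[c]["probs"]
                draws = rng.choice(list(BASES), size=len(unique_genera), p=probs)
                for g, b in zip(unique_genera, draws):
                    cons[g].append(b)
            cons_str = {g: "".join(v) for g, v in cons.items()}
            genus_consensus[seg.name] = cons_str
            for r, genus in enumerate(genera):
                for ci, c in enumerate(seg_cols):
                    mat[r, c] = cons_str[genus][ci]
        else:
            for c in seg_cols:
                m = models[c]
                if m["probs"].max() >= 1.0 - 1e-12:
                    mat[:, c] = m["major"]
                else:
                    mat[:, c] = rng.choice(list(BASES), size=n_rec, p=m["probs"])
        col += seg.length

    # plant sites
    site_records: dict[str, dict] = {}
    for site in spec.planted_sites:
        sense = site.sense_sequence
        cols = slice(site.ref_start - 1, site.ref_end)
        in_idx = [
            i for i, (_, tax) in enumerate(roster)
            if tax[0] == site.in_group_domain
        ]
        out_idx = [i for i in range(n_rec) if i not in set(in_idx)]
        n_present = round(site.presence * len(in_idx))
        chosen = sorted(
            rng.choice(in_idx, size=n_present, replace=False).tolist()
        ) if in_idx else []
        for i in chosen:
            mat[i, cols] = list(sense)
        mutated = _mutated_copy(sense, site.out_group_mismatches)
        for i in out_idx:
            mat[i, cols] = list(mutated)
        site_records[site.primer_id] = {
            "sequence": site.sequence,
            "orientation": site.orientation,
            "ref_start": site.ref_start,
            "ref_end": site.ref_end,
            "present_ids": [roster[i][0] for i in chosen],
            "out_group_ids": [roster[i][0] for i in out_idx],
            "out_group_site": mutated,
            "out_group_mismatches": site.out_group_mismatches,
        }

    # reference sequence: segment majors overridden by planted sites
    ref_chars = [models[c]["major"] for c in range(n_ref)]
    for site in spec.planted_sites:
        ref_chars[site.ref_start - 1 : site.ref_end] = list(site.sense_sequence)
    ref_seq = "".join(ref_chars)

    # weave in gap-only columns
    total_cols = n_ref + len(spec.gap_columns)
    gap_set = set(spec.gap_columns)
    src = iter(range(n_ref))
    order = [(-1 if c in gap_set else next(src)) for c in range(total_cols)]

    def weave(row: str) -> str:
        return "".join(GAP if j < 0 else row[j] for j in order)

    records = [
        Record(rid, weave("".join(mat[i])), tax)
        for i, (rid, tax) in enumerate(roster)
    ]
    if spec.include_reference:
        records.insert(0, Record(spec.reference_id, weave(ref_seq), REFERENCE_TAXONOMY))
    db = AlignedDatabase(records, total_cols, source_tag=f"synthetic(seed={spec.seed})")

    profile, blocks = reference_layout_report(spec)
    f_sites = [s for s in spec.planted_sites if s.orientation == "forward"]
    r_sites = [s for s in spec.planted_sites if s.orientation == "reverse"]
    amp_len = None
    if f_sites and r_sites:
        f0, r0 = f_sites[0], r_sites[0]
        if r0.ref_end > f0.ref_start:
            amp_len = r0.ref_end - f0.ref_start + 1
    truth = GroundTruth(
        ref_length=n_ref,
        expected_entropy=profile.values,
        expected_blocks=blocks,
        site_records=site_records,
        gap_columns=sorted(spec.gap_columns),
        genus_consensus=genus_consensus,
        expected_amplicon_length=amp_len,
    )
    return db, truth


def reference_layout_report(
    spec: FixtureSpec, criteria: BlockCriteria = BlockCriteria()
) -> tuple[EntropyProfile, list[ConservedBlock]]:
    """Analytic in-group entropy per reference position and expected blocks.

    Re-derives the per-column models from the seed, overlays planted-site
    mixtures (site base with the presence fraction, background otherwise),
    and runs the block detector on the analytic profile.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    models = _column_models(spec, rng)
    values = np.array([_mixture_entropy(m["probs"]) for m in models])
    for site in spec.planted_sites:
        sense = site.sense_sequence
        for off, base in enumerate(sense):
            c = site.ref_start - 1 + off
            bg = models[c]["probs"]
            mix = (1.0 - site.presence) * bg.copy()
            mix[BASES.index(base)] += site.presence
            values[c] = _mixture_entropy(mix)
    cmap = CoordinateMap(spec.reference_id, tuple(range(len(values))))
    profile = EntropyProfile(spec.reference_id, values, cmap)
    return profile, find_conserved_blocks(profile, criteria)


# ---------------------------------------------------------------------------
# canonical specs used across tests, examples and the acceptance script

#: Planted universal pair used by the parameter-recovery fixture: published
#: universal eukaryote 18S primers with a comfortable delta-Tm.
PLANTED_FORWARD = "CAGCAGCCGCGGTAATTCC"    # F-566 site sequence
PLANTED_REVERSE = "ACTAAGAACGGCCATGCACC"   # R-1289 site sequence

_EUK_GROUPS = [
    TaxonGroup("Eukaryota", "Annelida", "Polychaeta", "Phyllodocida",
               "Nereididae", "Nereis", 12),
    TaxonGroup("Eukaryota", "Arthropoda", "Hexanauplia", "Calanoida",
               "Calanidae", "Calanus", 12),
    TaxonGroup("Eukaryota", "Chlorophyta", "Mamiellophyceae", "Mamiellales",
               "Bathycoccaceae", "Ostreococcus", 12),
    TaxonGroup("Eukaryota", "Ciliophora", "Spirotrichea", "Choreotrichida",
               "Strombidiidae", "Strombidium", 12),
    TaxonGroup("Eukaryota", "Dinoflagellata", "Dinophyceae", "Gymnodiniales",
               "Gymnodiniaceae", "Gymnodinium", 12),
]
_PROK_GROUPS = [
    TaxonGroup("Bacteria", "Proteobacteria", "Gammaproteobacteria",
               "Alteromonadales", "Alteromonadaceae", "Alteromonas", 10),
    TaxonGroup("Bacteria", "Bacteroidota", "Flavobacteriia",
               "Flavobacteriales", "Flavobacteriaceae", "Polaribacter", 10),
    TaxonGroup("Archaea", "Thermoproteota", "Nitrososphaeria",
               "Nitrosopumilales", "Nitrosopumilaceae", "Nitrosopumilus", 10),
]


def design_recovery_spec(seed: int = 0) -> FixtureSpec:
    """Planted-pair fixture: one universal forward and reverse site within
    conserved blocks, out-group copies at Hamming distance 3, variable
    flanks, two gap-only columns, and an expected 620 nt amplicon."""
    segments = [
        Segment("v_left", 100, 1.5),
        Segment("f_block", len(PLANTED_FORWARD), 0.0),
        Segment("insert", 581, 1.2),
        Segment("r_block", len(PLANTED_REVERSE), 0.0),
        Segment("v_right", 80, 1.5),
    ]
    sites = [
        PlantedSite(PLANTED_FORWARD, "forward", 101,
                    out_group_mismatches=3),
        PlantedSite(PLANTED_REVERSE, "reverse", 701,
                    out_group_mismatches=3),
    ]
    return FixtureSpec(
        segments=segments,
        groups=_EUK_GROUPS + _PROK_GROUPS,
        planted_sites=sites,
        gap_columns=[0, 450],
        seed=seed,
    )


def resolution_spec(seed: int = 0, n_per_genus: int = 6) -> FixtureSpec:
    """Two genus-structured regions of contrasting entropy for resolution
    curves: records of a genus are identical within a region, genera diverge
    according to the region's per-column entropy target."""
    segments = [
        Segment("spacer_a", 20, 0.0),
        Segment("high_entropy", 100, 1.8, genus_structured=True),
        Segment("spacer_b", 20, 0.0),
        Segment("low_entropy", 100, 0.05, genus_structured=True),
        Segment("spacer_c", 20, 0.0),
    ]
    groups = [
        TaxonGroup("Eukaryota", "Annelida", "Polychaeta", "Phyllodocida",
                   "Nereididae", genus, n_per_genus)
        for genus in ("GenusA", "GenusB", "GenusC", "GenusD", "GenusE")
    ]
    return FixtureSpec(segments=segments, groups=groups, seed=seed)
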