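"""Aligned SSU rRNA database: parsing, taxonomy, gap columns, reference map.

The central container is :class:`AlignedDatabase`, a SILVA-style multiple
sequence alignment in which every record carries a semicolon-delimited
taxonomic path (domain;phylum;...;genus). Taxonomy can come from the FASTA
header (``>id Eukaryota;Opisthokonta;...;Saccharomyces``) or from a sidecar
TSV; when both are present and disagree, the header wins with a warning.

Alignment columns are 0-based internally; all user-facing coordinates on the
reference gene are 1-based (matching conventional primer names like F-566).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import GAP, normalize_sequence

log = logging.getLogger(__name__)

DOMAINS = ("Bacteria", "Archaea", "Eukaryota")
#: Standard rank order used throughout: index into a taxonomy path.
RANKS = ("domain", "phylum", "class", "order", "family", "genus")
RANK_INDEX = {r: i for i, r in enumerate(RANKS)}


class FormatError(ValueError):
    """Malformed alignment input (e.g. unequal sequence lengths)."""


class AnnotationError(ValueError):
    """A record without resolvable taxonomy."""


@dataclass(frozen=True)
class Record:
    id: str
    seq: str
    taxonomy: tuple[str, ...]
    #: Alignment-derived taxonomy, when it differs from the primary one
    #: (used to resolve records whose primary domain is "Ambiguous").
    alignment_taxonomy: tuple[str, ...] | None = None

    @property
    def domain(self) -> str:
        return self.taxonomy[0]

    def rank_label(self, rank: str) -> str | None:
        """Taxon label at *rank*, or None if the path is too shallow."""
        i = RANK_INDEX[rank]
        return self.taxonomy[i] if i < len(self.taxonomy) else None

    @property
    def ungapped(self) -> str:
        return self.seq.replace(GAP, "")


@dataclass
class AlignedDatabase:
    """An aligned sequence collection with per-record taxonomy."""

    records: list[Record]
    alignment_length: int
    source_tag: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if len(rec.seq) != self.alignment_length:
                raise FormatError(
                    f"record {rec.id!r} has length {len(rec.seq)}, "
                    f"expected {self.alignment_length}"
                )
            if not rec.taxonomy:
                raise AnnotationError(f"record {rec.id!r} has no taxonomy")
            if rec.domain not in DOMAINS + ("Ambiguous",):
                raise AnnotationError(
                    f"record {rec.id!r} has unknown domain {rec.domain!r}"
                )
            if rec.id in seen:
                raise FormatError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, record_id: str) -> Record:
        for rec in self.records:
            if rec.id == record_id:
                return rec
        raise KeyError(f"record id {record_id!r} not in database")

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def column(self, index: int) -> list[str]:
        """Characters of alignment column *index* (0-based), in record order."""
        return [rec.seq[index] for rec in self.records]

    def char_matrix(self) -> np.ndarray:
        """(n_records, alignment_length) array of single characters."""
        return np.array([list(r.seq) for r in self.records], dtype="U1")


@dataclass(frozen=True)
class CoordinateMap:
    """Maps reference-gene positions onto alignment columns.

    ``ref_positions[i]`` is the 0-based alignment column holding reference
    base ``i+1`` (1-based reference coordinates).
    """

    ref_id: str
    ref_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        pos = self.ref_positions
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("ref_positions must be strictly increasing")

    @property
    def ref_length(self) -> int:
        return len(self.ref_positions)

    def column_of(self, ref_pos: int) -> int:
        """Alignment column (0-based) of 1-based reference position."""
        if not 1 <= ref_pos <= self.ref_length:
            raise IndexError(f"reference position {ref_pos} out of range")
        return self.ref_positions[ref_pos - 1]

    def columns_of_range(self, start: int, end: int) -> tuple[int, ...]:
        """Alignment columns of the 1-based inclusive range [start, end]."""
        if not (1 <= start <= end <= self.ref_length):
            raise IndexError(f"reference range {start}..{end} out of range")
        return self.ref_positions[start - 1 : end]


@dataclass(frozen=True)
class ColumnRemovalReport:
    """Non-gap content of alignment columns slated for removal."""

    removed_columns: tuple[int, ...]
    per_column_nongap_fraction: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.removed_columns) != len(self.per_column_nongap_fraction):
            raise ValueError("column and fraction lists differ in length")
        if any(not 0.0 <= f <= 1.0 for f in self.per_column_nongap_fraction):
            raise ValueError("fractions must lie in [0, 1]")

    @property
    def mean_fraction(self) -> float:
        if not self.per_column_nongap_fraction:
            return 0.0
        return float(np.mean(self.per_column_nongap_fraction))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("column_index\tnongap_fraction\n")
            for col, frac in zip(
                self.removed_columns, self.per_column_nongap_fraction
            ):
                fh.write(f"{col}\t{frac:.6g}\n")


def _parse_taxonomy(text: str) -> tuple[str, ...]:
    path = tuple(t.strip() for t in text.strip().split(";") if t.strip())
    if not path:
        raise AnnotationError(f"empty taxonomy string: {text!r}")
    return path


def read_taxonomy_tsv(path: str | Path) -> dict[str, tuple[tuple[str, ...], tuple[str, ...] | None]]:
    """Read a sidecar taxonomy TSV.

    Columns: record id, semicolon path, optional alignment-derived path.
    """
    table: dict[str, tuple[tuple[str, ...], tuple[str, ...] | None]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(
                    f"{path}:{line_no}: expected at least 2 tab-separated fields"
                )
            rid, tax = parts[0], _parse_taxonomy(parts[1])
            alt = _parse_taxonomy(parts[2]) if len(parts) > 2 and parts[2].strip() else None
            table[rid] = (tax, alt)
    return table


def read_aligned_fasta(
    path: str | Path,
    taxonomy_source: str | Path | None = None,
    source_tag: str = "",
) -> AlignedDatabase:
    """Read an aligned FASTA with taxonomy from headers and/or a sidecar TSV.

    'U' is normalized to 'T' and '.' to '-'; sequences are uppercased.
    Header taxonomy (description after the id) takes precedence over the
    sidecar on conflict, with a logged warning.
    """
    sidecar = read_taxonomy_tsv(taxonomy_source) if taxonomy_source else {}
    records: list[Record] = []
    for sr in SeqIO.parse(str(path), "fasta"):
        try:
            seq = normalize_sequence(str(sr.seq))
        except ValueError as exc:
            raise FormatError(f"record {sr.id!r}: {exc}") from exc
        header_tax: tuple[str, ...] | None = None
        desc = sr.description[len(sr.id):].strip()
        if desc:
            header_tax = _parse_taxonomy(desc)
        side = sidecar.get(sr.id)
        alignment_tax = side[1] if side else None
        if header_tax and side and header_tax != side[0]:
            log.warning(
                "record %s: header taxonomy %s overrides sidecar %s",
                sr.id, ";".join(header_tax), ";".join(side[0]),
            )
        taxonomy = header_tax or (side[0] if side else None)
        if taxonomy is None:
            raise AnnotationError(
                f"record {sr.id!r} has no taxonomy in header or sidecar"
            )
        records.append(Record(sr.id, seq, taxonomy, alignment_tax))
    if not records:
        raise FormatError(f"no records in {path}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise FormatError(f"unequal aligned lengths in {path}: {sorted(lengths)}")
    return AlignedDatabase(records, lengths.pop(), source_tag or str(path))


def write_aligned_fasta(
    db: AlignedDatabase,
    path: str | Path,
    taxonomy_tsv: str | Path | None = None,
) -> None:
    """Write the alignment with header taxonomy; optionally a sidecar TSV."""
    seqrecords = [
        SeqRecord(Seq(r.seq), id=r.id, description=";".join(r.taxonomy))
        for r in db.records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")
    if taxonomy_tsv is not None:
        with open(taxonomy_tsv, "w") as fh:
            for r in db.records:
                alt = ";".join(r.alignment_taxonomy) if r.alignment_taxonomy else ""
                fh.write(f"{r.id}\t{';'.join(r.taxonomy)}\t{alt}\n")


def filter_by_domain(
    db: AlignedDatabase,
    keep: set[str],
    ambiguity_policy: str = "alignment",
) -> AlignedDatabase:
    """Keep only records whose domain is in *keep*.

    Records labeled "Ambiguous" are resolved per *ambiguity_policy*:
    ``"alignment"`` (default) substitutes the alignment-derived taxonomy when
    available, mirroring curation practice that prefers the alignment-based
    annotation; ``"drop"`` removes them; ``"keep"`` retains them verbatim.
    """
    if not keep <= set(DOMAINS):
        raise ValueError(f"keep must be a subset of {DOMAINS}, got {keep}")
    kept: list[Record] = []
    for rec in db.records:
        if rec.domain == "Ambiguous":
            if ambiguity_policy == "drop":
                continue
            if ambiguity_policy == "alignment" and rec.alignment_taxonomy:
                rec = replace(rec, taxonomy=rec.alignment_taxonomy)
            elif ambiguity_policy == "keep":
                if "Ambiguous" in keep:  # pragma: no cover - keep is domain-only
                    kept.append(rec)
                continue
            else:
                continue
        if rec.domain in keep:
            kept.append(rec)
    if not kept:
        warnings.warn(f"filter_by_domain(keep={sorted(keep)}) left no records")
    return AlignedDatabase(kept, db.alignment_length, db.source_tag)


def drop_gap_only_columns(
    db: AlignedDatabase,
) -> tuple[AlignedDatabase, list[int]]:
    """Remove columns that are gaps in every record.

    Returns the reduced database and the removed column indices (0-based,
    ascending). Relative order of kept columns is preserved.
    """
    if not db.records:
        return db, []
    mat = db.char_matrix()
    gap_only = (mat == GAP).all(axis=0)
    removed = np.flatnonzero(gap_only)
    if removed.size == 0:
        return db, []
    keep = ~gap_only
    new_records = [
        replace(rec, seq="".join(mat[i, keep]))
        for i, rec in enumerate(db.records)
    ]
    new_len = int(keep.sum())
    out = AlignedDatabase(new_records, new_len, db.source_tag)
    return out, [int(c) for c in removed]


def map_to_reference(db: AlignedDatabase, ref_id: str) -> CoordinateMap:
    """Coordinate map from the reference record's non-gap columns."""
    ref = db.get(ref_id)
    positions = tuple(i for i, c in enumerate(ref.seq) if c != GAP)
    if not positions:
        warnings.warn(f"reference {ref_id!r} is all gaps; empty coordinate map")
    return CoordinateMap(ref_id, positions)


def information_loss(
    db: AlignedDatabase, candidate_removed_columns: list[int]
) -> ColumnRemovalReport:
    """Per-column non-gap fraction for columns slated for removal.

    Quantifies how much sequence information dropping those columns loses:
    a fraction near 0 means the column is almost pure gap.
    """
    n = len(db.records)
    fractions: list[float] = []
    for col in candidate_removed_columns:
        if not 0 <= col < db.alignment_length:
            raise IndexError(f"column {col} out of range")
        nongap = sum(1 for c in db.column(col) if c != GAP)
        fractions.append(nongap / n if n else 0.0)
    return ColumnRemovalReport(tuple(candidate_removed_columns), tuple(fractions))
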