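"""Taxonomic resolution of gene regions by identity clustering.

For a region of the reference gene (a hypervariable region V1-V9 or an
arbitrary amplicon), each record's ungapped segment is extracted through the
coordinate map, segments are clustered by complete-linkage agglomeration on
pairwise-identity distance at a series of cutoffs (typically 100% down to
95%), and two curves are reported per cutoff: the raw cluster count and the
number of "distinguishable" in-group genera — genera that are the majority
label of at least one cluster.

Identity between two segments is matches / aligned columns of a global
pairwise alignment scored match=1, mismatch=0, gap=-0.5 (internal and
terminal gaps count as columns).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import Align
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .database_io import GAP, AlignedDatabase, CoordinateMap

DEFAULT_CUTOFFS = (1.00, 0.99, 0.98, 0.97, 0.96, 0.95)
MAX_SEGMENTS_DEFAULT = 5000


@dataclass(frozen=True)
class RegionDefinition:
    """A named 1-based inclusive range on the reference gene."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"region {self.name}: start must be < end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def read_regions_tsv(path: str | Path) -> list[RegionDefinition]:
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].lower() == "name":
                continue
            regions.append(
                RegionDefinition(parts[0], int(parts[1]), int(parts[2]))
            )
    return regions


def extract_region(
    db: AlignedDatabase,
    cmap: CoordinateMap,
    region: RegionDefinition,
) -> tuple[dict[str, str], int]:
    """Per-record ungapped segment over the region's mapped columns.

    Insertions relative to the reference fall between mapped columns and are
    therefore excluded. Records that are all-gap over the region are dropped
    and counted. Returns (segments by record id, dropped count).
    """
    cols = cmap.columns_of_range(region.start, region.end)
    segments: dict[str, str] = {}
    dropped = 0
    for rec in db.records:
        seg = "".join(rec.seq[c] for c in cols).replace(GAP, "")
        if seg:
            segments[rec.id] = seg
        else:
            dropped += 1
    return segments, dropped


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1.0
    a.mismatch_score = 0.0
    a.open_gap_score = -0.5
    a.extend_gap_score = -0.5
    return a


def pairwise_identity(a: str, b: str) -> float:
    """Matches / aligned columns of a global alignment; symmetric in (a, b).

    The first optimal traceback of the aligner is used, which is
    deterministic for fixed inputs; arguments are ordered canonically
    before aligning, so co-optimal-alignment choices cannot break symmetry.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    if a == b:
        return 1.0
    if (len(a), a) > (len(b), b):
        a, b = b, a
    aln = _aligner().align(a, b)[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / columns


def identity_matrix(segments: list[str]) -> np.ndarray:
    """Symmetric pairwise identity matrix (diagonal 1)."""
    n = len(segments)
    mat = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = pairwise_identity(segments[i], segments[j])
    return mat


def cluster_at_identity(
    segments: list[str],
    cutoff: float,
    method: str = "complete",
    max_segments: int = MAX_SEGMENTS_DEFAULT,
    precomputed_identity: np.ndarray | None = None,
) -> np.ndarray:
    """Cluster labels (1-based, ordered by first appearance of each cluster).

    Agglomerative clustering on distance 1 - identity, cut at 1 - cutoff:
    two segments land in one cluster iff their linkage distance is <= the
    cut, so segments at identity exactly equal to the cutoff co-cluster.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must be in [0, 1]")
    n = len(segments)
    if n > max_segments:
        raise ValueError(
            f"{n} segments exceeds max_segments={max_segments}: "
            "quadratic clustering is not intended for this scale"
        )
    if n == 0:
        return np.zeros(0, dtype=int)
    if n == 1:
        return np.ones(1, dtype=int)
    ident = (
        precomputed_identity
        if precomputed_identity is not None
        else identity_matrix(segments)
    )
    dist = 1.0 - ident
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    tree = linkage(condensed, method=method)
    raw = fcluster(tree, t=1.0 - cutoff + 1e-12, criterion="distance")
    # relabel deterministically by input order of first appearance
    remap: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, lab in enumerate(raw):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        labels[i] = remap[lab]
    return labels


@dataclass
class ResolutionCurve:
    """Cluster and distinguishable-genus counts across identity cutoffs."""

    region_name: str
    cutoffs: tuple[float, ...]
    cluster_counts: tuple[int, ...]
    distinguishable_genus_counts: tuple[int, ...]
    n_segments: int
    dropped_records: int

    def to_tsv(self, path: str | Path, append: bool = False) -> None:
        mode = "a" if append else "w"
        with open(path, mode) as fh:
            if not append:
                fh.write("region\tcutoff\tclusters\tdistinguishable_genera\n")
            for c, k, g in zip(
                self.cutoffs, self.cluster_counts,
                self.distinguishable_genus_counts,
            ):
                fh.write(f"{self.region_name}\t{c:.2f}\t{k}\t{g}\n")


def _distinguishable_genera(
    labels: np.ndarray, genera: list[str | None]
) -> int:
    """Genera that are the majority label of >= 1 cluster (ties: lexicographic)."""
    majority: set[str] = set()
    for cluster in np.unique(labels):
        members = [
            g for lab, g in zip(labels, genera) if lab == cluster and g
        ]
        if not members:
            continue
        counts: dict[str, int] = {}
        for g in members:
            counts[g] = counts.get(g, 0) + 1
        top = max(counts.values())
        majority.add(min(g for g, c in counts.items() if c == top))
    return len(majority)


def resolution_curve(
    db: AlignedDatabase,
    cmap: CoordinateMap,
    region: RegionDefinition,
    cutoffs=DEFAULT_CUTOFFS,
    method: str = "complete",
    max_segments: int = MAX_SEGMENTS_DEFAULT,
) -> ResolutionCurve:
    """Resolution of one region across identity cutoffs (sorted descending).

    Both the raw cluster count and the distinguishable-genus count are
    reported: they answer slightly different questions (how many sequence
    types the region separates, vs how many named genera those types can
    stand in for).
    """
    cutoffs = tuple(sorted(cutoffs, reverse=True))
    segments_by_id, dropped = extract_region(db, cmap, region)
    ids = list(segments_by_id)
    segments = [segments_by_id[i] for i in ids]
    genera = [db.get(i).rank_label("genus") for i in ids]
    if not segments:
        return ResolutionCurve(
            region.name, cutoffs, tuple(0 for _ in cutoffs),
            tuple(0 for _ in cutoffs), 0, dropped,
        )
    ident = identity_matrix(segments)
    cluster_counts = []
    genus_counts = []
    for cutoff in cutoffs:
        labels = cluster_at_identity(
            segments, cutoff, method, max_segments, precomputed_identity=ident
        )
        cluster_counts.append(int(labels.max()))
        genus_counts.append(_distinguishable_genera(labels, genera))
    return ResolutionCurve(
        region.name, cutoffs, tuple(cluster_counts), tuple(genus_counts),
        len(segments), dropped,
    )
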