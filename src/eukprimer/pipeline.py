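"""End-to-end design pipeline: alignment in, ranked primer pairs out.

The stages follow the field's standard workflow: restrict the alignment to
the target domain, drop gap-only columns, map onto the reference gene,
profile per-position entropy, detect conserved blocks, grow primer
candidates out of block consensus seeds while scoring every step against
the full database (prokaryotes included), prune by the selection criteria,
and pair survivors under amplicon-length and delta-Tm constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .database_io import (
    AlignedDatabase, CoordinateMap, drop_gap_only_columns, filter_by_domain,
    map_to_reference,
)
from .entropy import (
    BlockCriteria, ConservedBlock, EntropyProfile, entropy_profile,
    find_conserved_blocks,
)
from .primer_design import (
    ExtensionConfig, PairConfig, PrimerCandidate, PrimerPair, Rejection,
    Seed, SelectionConfig, apply_selection_criteria, extend_candidate,
    seeds_from_blocks, select_pairs,
)


@dataclass
class DesignResult:
    target_db: AlignedDatabase
    removed_columns: list[int]
    coordinate_map: CoordinateMap
    profile: EntropyProfile
    blocks: list[ConservedBlock]
    seeds: list[Seed]
    trace: list[PrimerCandidate]
    kept: list[PrimerCandidate]
    rejections: list[Rejection]
    pairs: list[PrimerPair] = field(default_factory=list)

    @property
    def top_pair(self) -> PrimerPair | None:
        return self.pairs[0] if self.pairs else None


def _best_window(
    block: ConservedBlock, profile: EntropyProfile, width: int,
    threshold: float = 0.2,
) -> ConservedBlock:
    """Lowest-mean-entropy window of a block wider than a primer (ties: left)."""
    import numpy as np

    vals = profile.values[block.start - 1 : block.end]
    best_s, best_mean = 0, float("inf")
    for s in range(0, block.length - width + 1):
        m = float(np.nanmean(vals[s : s + width]))
        if m < best_mean - 1e-12:
            best_s, best_mean = s, m
    start = block.start + best_s
    window = profile.values[start - 1 : start - 1 + width]
    below = np.where(np.isfinite(window), window < threshold, False)
    return ConservedBlock(start, start + width - 1, float(below.mean()), best_mean)


def run_design(
    db: AlignedDatabase,
    ref_id: str,
    target_domain: str = "Eukaryota",
    block_criteria: BlockCriteria = BlockCriteria(),
    extension: ExtensionConfig | None = None,
    selection: SelectionConfig = SelectionConfig(),
    pairing: PairConfig | None = None,
) -> DesignResult:
    """Run the whole design pipeline on an aligned, annotated database.

    Entropy profiling and block detection see only the target domain;
    candidate scoring and pairing see the full database, which is what
    makes out-group (prokaryote) exclusion measurable.
    """
    extension = extension or ExtensionConfig(target_domain=target_domain)
    pairing = pairing or PairConfig(target_domain=target_domain)
    target = filter_by_domain(db, {target_domain})
    target, removed = drop_gap_only_columns(target)
    cmap = map_to_reference(target, ref_id)
    profile = entropy_profile(target, cmap)
    blocks = find_conserved_blocks(profile, block_criteria)
    seed_blocks = [
        b if b.length <= extension.max_length
        else _best_window(b, profile, extension.max_length,
                          block_criteria.entropy_threshold)
        for b in blocks
    ]
    seeds = seeds_from_blocks(seed_blocks, target, cmap)
    trace: list[PrimerCandidate] = []
    for seed in seeds:
        trace.extend(extend_candidate(seed, db, cmap, extension))
    kept, rejections = apply_selection_criteria(trace, selection)
    forwards = [c for c in kept if c.orientation == "forward"]
    reverses = [c for c in kept if c.orientation == "reverse"]
    pairs = select_pairs(forwards, reverses, db, pairing)
    return DesignResult(
        target_db=target, removed_columns=removed, coordinate_map=cmap,
        profile=profile, blocks=blocks, seeds=seeds, trace=trace,
        kept=kept, rejections=rejections, pairs=pairs,
    )
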