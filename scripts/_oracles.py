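"""Brute-force oracles used by the acceptance script.

Independent re-implementations of the block rule and of mismatch-tolerant
primer matching: straightforward enumeration, no shared code with the
package's optimized paths.
"""

from __future__ import annotations

from eukprimer.alphabet import IUPAC_SETS
from eukprimer.entropy import BlockCriteria


def oracle_blocks(values, criteria: BlockCriteria = BlockCriteria()):
    """Leftmost-longest enumeration of qualifying conserved windows.

    A window qualifies iff it starts and ends below the entropy threshold,
    spans >= min_length positions, and >= min_fraction of its positions lie
    below the threshold (NaN counts as not-below).
    """
    vals = list(values)
    n = len(vals)
    L, f, t = (criteria.min_length, criteria.min_fraction_below,
               criteria.entropy_threshold)
    below = [(v == v) and v < t for v in vals]

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


def oracle_min_mismatches(seq: str, probe: str) -> int:
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
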