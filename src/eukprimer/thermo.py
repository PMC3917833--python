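"""Primer-intrinsic physical checks: GC%, melting temperature, clamps, duplexes.

Melting temperatures use the unified nearest-neighbor parameter set
(SantaLucia-style dH/dS table) at 50 mM monovalent salt and 0.25 uM oligo,
the common oligo-vendor default. Hairpin and dimer screens count contiguous
Watson-Crick complementary runs rather than folding free energies: the
criteria are deterministic and directly checkable by exhaustive enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.SeqUtils import MeltingTemp as _mt

from .alphabet import complement, is_unambiguous

#: Nearest-neighbor parameter choices exposed to callers.
NN_TABLES = {
    "santalucia_unified": _mt.DNA_NN3,  # Allawi & SantaLucia unified set
    "santalucia_2004": _mt.DNA_NN4,
    "sugimoto": _mt.DNA_NN2,
}

DEFAULT_TM_PARAMS = {
    "table": "santalucia_unified",
    "na_mM": 50.0,
    "oligo_uM": 0.25,
}

DIMER_RUN_THRESHOLD = 8
HAIRPIN_MIN_STEM = 4
HAIRPIN_MIN_LOOP = 3


class AmbiguousSequenceError(ValueError):
    """Raised when a calculation requires an unambiguous A/C/G/T sequence."""


def _require_unambiguous(seq: str, what: str) -> None:
    if not seq:
        raise ValueError(f"{what}: empty sequence")
    if not is_unambiguous(seq):
        raise AmbiguousSequenceError(
            f"{what}: ambiguity codes present in {seq!r}; "
            "expand degeneracy and compute per expansion"
        )


def gc_percent(seq: str) -> float:
    """Percent of G+C bases, reported to 1 decimal."""
    _require_unambiguous(seq, "gc_percent")
    gc = sum(1 for c in seq if c in "GC")
    return round(100.0 * gc / len(seq), 1)


def melting_temperature(
    seq: str,
    table: str = DEFAULT_TM_PARAMS["table"],
    na_mM: float = DEFAULT_TM_PARAMS["na_mM"],
    oligo_uM: float = DEFAULT_TM_PARAMS["oligo_uM"],
) -> float:
    """Nearest-neighbor melting temperature in Celsius.

    Deterministic for a fixed parameter set; primers of 6-60 nt only.
    """
    _require_unambiguous(seq, "melting_temperature")
    if not 6 <= len(seq) <= 60:
        raise ValueError(
            f"melting_temperature: length {len(seq)} outside supported 6..60"
        )
    return float(
        _mt.Tm_NN(
            seq,
            nn_table=NN_TABLES[table],
            Na=na_mM,
            dnac1=oligo_uM * 1000.0,  # Tm_NN takes nM
            dnac2=0,
        )
    )


def gc_clamp(seq: str, rule: str = "last3") -> bool:
    """3'-end GC clamp check.

    ``"last3"``: at least 2 of the final 3 bases are G/C.
    ``"last5"``: the final 5 bases contain exactly 2 or 3 G/C.
    """
    _require_unambiguous(seq, "gc_clamp")
    if len(seq) < 5:
        raise ValueError("gc_clamp: sequence shorter than 5 nt")
    if rule == "last3":
        return sum(1 for c in seq[-3:] if c in "GC") >= 2
    if rule == "last5":
        return sum(1 for c in seq[-5:] if c in "GC") in (2, 3)
    raise ValueError(f"unknown GC clamp rule {rule!r}")


def max_complement_run(seq_a: str, seq_b: str) -> int:
    """Longest contiguous WC-complementary run over all ungapped offsets.

    Models antiparallel annealing of two oligos: *seq_a* 5'->3' is slid
    against *seq_b* reversed, and the longest stretch of consecutive
    complementary pairs over any offset is returned.
    """
    _require_unambiguous(seq_a, "max_complement_run")
    _require_unambiguous(seq_b, "max_complement_run")
    b_rev = seq_b[::-1]
    best = 0
    for offset in range(-(len(b_rev) - 1), len(seq_a)):
        run = 0
        for i, ca in enumerate(seq_a):
            j = i - offset
            if 0 <= j < len(b_rev) and complement(ca) == b_rev[j]:
                run += 1
                best = max(best, run)
            else:
                run = 0
    return best


def has_hairpin(
    seq: str,
    min_stem: int = HAIRPIN_MIN_STEM,
    min_loop: int = HAIRPIN_MIN_LOOP,
) -> bool:
    """True if any self-complementary stem of >= *min_stem* bp can fold back
    over a loop of >= *min_loop* unpaired bases."""
    _require_unambiguous(seq, "has_hairpin")
    n = len(seq)
    from .alphabet import reverse_complement

    for stem in range(min_stem, n // 2 + 1):
        for i in range(0, n - stem + 1):
            arm = seq[i : i + stem]
            target = reverse_complement(arm)
            for j in range(i + stem + min_loop, n - stem + 1):
                if seq[j : j + stem] == target:
                    return True
    return False


def duplex_screen(
    seq_a: str,
    seq_b: str | None = None,
    run_threshold: int = DIMER_RUN_THRESHOLD,
) -> tuple[int, bool]:
    """Dimer screen: (max complementary run, flag run >= threshold).

    With *seq_b* omitted the screen is against *seq_a* itself (self-dimer).
    """
    run = max_complement_run(seq_a, seq_b if seq_b is not None else seq_a)
    return run, run >= run_threshold


@dataclass(frozen=True)
class ThermoProfile:
    """Physical summary of one primer, mirroring a primer-table row."""

    gc_percent: float
    tm_celsius: float
    gc_clamp_3of3: bool
    gc_clamp_5prime_rule: bool
    hairpin_flag: bool
    self_dimer_flag: bool
    max_complement_run: int


def thermo_profile(seq: str, **tm_kwargs) -> ThermoProfile:
    """Compute the full :class:`ThermoProfile` for one unambiguous primer."""
    run, dimer = duplex_screen(seq)
    return ThermoProfile(
        gc_percent=gc_percent(seq),
        tm_celsius=melting_temperature(seq, **tm_kwargs),
        gc_clamp_3of3=gc_clamp(seq, "last3"),
        gc_clamp_5prime_rule=gc_clamp(seq, "last5"),
        hairpin_flag=has_hairpin(seq),
        self_dimer_flag=dimer,
        max_complement_run=run,
    )
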