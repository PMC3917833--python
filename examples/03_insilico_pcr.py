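"""Mismatch-tolerant in silico PCR and taxonomic coverage reporting.

Runs the planted universal pair against every record of the fixture at
k = 0, 1, 2 allowed mismatches per primer. At k=0 only the in-group
(eukaryote) phyla amplify; the out-group sites carry 3 substitutions, so
prokaryotes stay excluded even at k=2 — the safety margin the two-mismatch
robustness test is after.
"""

from eukprimer import (
    amplicon_length_distribution, amplify, coverage_by_rank,
    design_recovery_spec, generate,
)
from eukprimer.fixtures import PLANTED_FORWARD, PLANTED_REVERSE

db, _ = generate(design_recovery_spec(seed=1))

for k in (0, 1, 2):
    report = coverage_by_rank(db, PLANTED_FORWARD, PLANTED_REVERSE,
                              rank="phylum", k=k)
    print(f"k={k}: {report.groups_covered}/{report.groups_total} phyla "
          f"covered; excluded: {report.excluded_groups or 'none'}")

amplicons = []
for rec in db.records:
    amplicons.extend(
        amplify(rec.ungapped, PLANTED_FORWARD, PLANTED_REVERSE, 0, rec.id)
    )
dist = amplicon_length_distribution(amplicons, window=(530, 700))
print(f"\n{dist.n} amplicons: mean {dist.mean:.0f} nt "
      f"(min {dist.min}, max {dist.max}); "
      f"{dist.fraction_in_window:.0%} inside {dist.window} nt")
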