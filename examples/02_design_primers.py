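"""End-to-end primer design on a fixture with a planted universal pair.

The fixture plants the published universal eukaryote primers F-566 and
R-1289 as perfectly conserved eukaryote sites (absent at Hamming distance 3
from all prokaryote records). The design pipeline should rediscover exactly
that pair from the entropy structure alone and rank it first.
"""

from eukprimer import design_recovery_spec, generate, run_design

db, truth = generate(design_recovery_spec(seed=1))
result = run_design(db, "REF")

print(f"{len(result.blocks)} conserved blocks -> {len(result.seeds)} seeds "
      f"-> {len(result.trace)} candidates "
      f"({len(result.kept)} kept, {len(result.rejections)} rejected)")
for r in result.rejections:
    print(f"  rejected {r.candidate_id}: {', '.join(r.reasons)}")

print("\nranked pairs (coverage = fraction of eukaryote records amplified):")
for p in result.pairs:
    print(f"  {p.id:<13} dTm {p.delta_tm:4.2f} C  "
          f"amplicon mean {p.amplicon_stats.mean:.0f} nt  "
          f"coverage {p.joint_coverage_fraction:.0%}  "
          f"prokaryote hits k<=2: {p.prokaryote_joint_hits[2]}")

top = result.top_pair
print(f"\ntop pair: {top.forward.id} 5'-{top.forward.sequence}-3'  +  "
      f"{top.reverse.id} 5'-{top.reverse.sequence}-3'")
print("matches planted pair:",
      top.forward.sequence == truth.site_records["F-101"]["sequence"]
      and top.reverse.sequence == truth.site_records["R-720"]["sequence"])
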