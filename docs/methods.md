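# Methods

## Scope and model

`eukprimer` treats universal primer design as a constrained search over a
taxonomically annotated multiple sequence alignment of SSU rRNA genes.
The alignment is the model: per-column nucleotide frequencies stand in
for the distribution of sequence states across the target group, and all
downstream quantities (entropy, consensus, hit counts, coverage,
resolution) are deterministic functions of it. No phylogenetic model is
fitted; columns are treated independently everywhere.

Coordinates follow the field's convention: alignment columns are 0-based
internally, while everything user-facing is 1-based on the reference
gene, so a primer id like `F-566` names the 5′-terminus position of the
primer on the reference. Reverse primers are stored 5′→3′ as synthesized
(reverse complement of the sense strand); their id uses the *end* of the
sense footprint, which is the primer's 5′ terminus.

## Entropy and conserved blocks

Column entropy is Shannon entropy over {A, C, G, T} in bits (log base 2,
configurable to natural log in `shannon_entropy`). The 0–2 bit scale
matches the four-symbol alphabet, and the 0.2-bit block threshold is
meaningful on it (~97% majority base). Ambiguity codes contribute 1/|S|
to each member of their set; gaps contribute nothing, because
conservation is a statement about the nucleotides that are present.
Columns with no nucleotide at all (possible after domain filtering) get a
NaN sentinel and never count as conserved.

Block detection uses the rule: ≥ `min_length` (10) positions with
≥ `min_fraction_below` (0.90) of them under `entropy_threshold` (0.2
bits). Two refinements make the rule well-posed:

* **Boundary anchoring.** A qualifying window must start and end on
  below-threshold positions. Without this, any block of length L ≥ 9 can
  absorb a high-entropy overhang column (L/(L+1) ≥ 0.9), so detected
  blocks would generically carry variable edges — useless as primer
  anchors and visibly not "consecutive conserved positions".
* **Leftmost-longest emission.** Scanning left to right, the detector
  emits the window with the smallest qualifying start and, for that
  start, the largest qualifying end, then continues after it. Emitted
  blocks are disjoint, sorted, and cannot be extended by one position
  without violating a criterion. This makes the detector exactly
  reproducible by a brute-force enumeration oracle, which the tests and
  the acceptance script both exercise on randomized profiles.

## Thermodynamics

Melting temperatures use Biopython's nearest-neighbor implementation
with the unified SantaLucia-style ΔH/ΔS table (`DNA_NN3`), 50 mM
monovalent salt and 0.25 µM oligo — common vendor defaults. Published
primer Tm values were produced by a vendor tool with unpublished
settings, so the package's Tm is checked against them only within
±2.5 °C; with these parameters the worst deviation across the 14 bundled
primers is 1.8 °C. GC% is exact and reproduces all 14 printed values
after 1-decimal rounding.

Hairpin and dimer screens deliberately count Watson-Crick complementary
runs instead of folding ΔG: a self- or hetero-dimer flags at a contiguous
complementary run ≥ 8 bp over any ungapped antiparallel offset, a hairpin
at any self-complementary stem ≥ 4 bp folding back over a loop ≥ 3 nt.
These thresholds are declared, deterministic, and oracle-checkable;
full secondary-structure thermodynamics is out of scope.

Two 3′ GC-clamp phrasings circulate; both are implemented. The default
(`last3`) requires ≥ 2 G/C among the final 3 nt; the alternative
(`last5`) requires exactly 2–3 G/C among the final 5 nt (four or five
G/C-rich termini promote mispriming, hence the upper bound).

## Candidate generation and selection

Seeds are block majority consensus sequences (fractional counts, ties
broken A<C<G<T), taken in both orientations. Extension is greedy: at each
step both flanking columns are tried with all four bases, the extension
keeping the most exact in-group hits wins (ties: left flank, base order),
and every step is fully re-scored against the whole database. Extension
stops at 22 nt, at the reference bounds, or when the best step's in-group
coverage falls below `coverage_floor` (default 0.8 of in-group records) —
the quantitative stand-in for the qualitative "compromise between
maximal coverage and minimal inclusion". Blocks wider than a primer are
narrowed to their lowest-entropy window of maximum primer length before
seeding. An exhaustive both-flank trace is recorded, so every
intermediate of legal length is a candidate.

Selection enforces, in order: no degeneracy; zero prokaryote exact
matches (`max_prokaryote_exact` configurable); length 18–22 with a
short-exclusive exception (a shorter primer is kept iff it has zero
prokaryote hits at every k ≤ 2); the GC clamp; clean hairpin and
self-dimer screens. Every rejection is logged with all violated
criteria. "Hits" count sequence records, not collapsed taxa: record-level
counting is what coverage fractions are defined over.

Pairing takes every F×R combination with the reverse footprint
downstream of the forward footprint, requires ΔTm < 5 °C and a mean
predicted amplicon under the hard cap (800 nt minus a configurable
tag/adapter allowance; 500–650 nt is the optimum window), and ranks by
joint in-group coverage, then by closeness of the mean amplicon length to
the optimum midpoint. Joint coverage is computed by actually amplifying
each in-group record at k = 0, so it automatically respects orientation,
ordering and site compatibility; it can never exceed either primer's own
coverage.

## In silico PCR

Matching is ungapped Hamming distance — primer annealing tolerates
substitutions far better than bulges, and mismatch robustness is the
quantity of interest. A primer base matches an ambiguous template base
iff it belongs to the code's set (strict mode available). Records are
assumed sense-oriented, as curated SSU databases are. When several site
pairs are compatible, the default `outermost` policy reports the longest
product (`innermost` and `all` are selectable). Coverage at a rank is a
boolean per group: ≥ 1 record with ≥ 1 amplicon at the given k, with
k = 0 as the "perfect match" default.

The hit-count machinery is bitmask-vectorized (A=1, C=2, G=4, T=8;
ambiguity codes OR their members; a window position mismatches when the
AND is zero) and is validated against an independent early-exit Hamming
scan in both the test suite and the acceptance script.

## Region resolution

Pairwise identity is matches / aligned columns of a global alignment
(match 1, mismatch 0, gap −0.5 per column, terminal gaps included),
computed with Biopython's `PairwiseAligner`; arguments are ordered
canonically before aligning so co-optimal tracebacks cannot break
symmetry. Identity is not uniquely defined across co-optimal alignments
of a fixed score, so the declared convention — first traceback of the
canonical orientation — is part of the method. Clustering is
complete-linkage agglomeration on distance 1 − identity, cut at
1 − cutoff; a pair at identity exactly equal to the cutoff co-clusters.
Labels are deterministic (input order of first appearance; cluster
majority-label ties break lexicographically). Both cluster counts and
distinguishable-genus counts are reported, since either can be the
quantity of interest. The quadratic cost is capped at 5,000 segments by
default; this module is not meant for UCLUST-scale greedy clustering.

Default V1–V9 coordinates ship as a data file labeled approximate;
region boundaries differ between structure models and users should
derive their own from their entropy profile.

## Synthetic fixtures

The generator emulates the features of a curated SSU database that the
pipeline actually consumes: designed per-column entropy (one majority
base with probability p solved numerically from the target entropy, the
other three bases equiprobable), planted primer sites present verbatim in
a chosen fraction of in-group records and carried with an exact number of
evenly spaced substitutions by every out-group record, gap-only columns,
hierarchical lineages, and an in-alignment reference record. Optional
genus-structured segments draw one consensus per genus so that identity
clustering has real taxonomic signal. Everything flows from one integer
seed; equal specs give byte-identical databases, and
`reference_layout_report` re-derives the analytic entropy profile and the
block set the detector must find.

What the fixtures do *not* model: phylogenetic covariance between
columns, indel length polymorphism within regions, chimeras, or
sequencing error. Passing tests therefore demonstrate the correctness of
the algorithms on alignments with known structure, not the biological
universality of any primer on real databases. Database-scale survey
numbers (coverage percentages over half a million reference sequences,
read and OTU counts from environmental runs) require those external
datasets and are deliberately out of scope; the fixture-based tests
exercise the same covered/excluded logic at desk scale.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| block min_length | 10 positions | minimum conserved-block span |
| block min_fraction_below | 0.90 | fraction of positions under threshold |
| entropy_threshold | 0.2 bits | "conserved position" cutoff |
| primer length | 18–22 nt | with short-exclusive exception |
| coverage_floor | 0.80 | extension stop, fraction of in-group |
| GC clamp | last3 (≥2 G/C) | `last5` selectable |
| ΔTm cap | 5 °C | pair co-amplification constraint |
| amplicon window | 500–650 opt, <800 hard | sequencing-platform driven |
| k (mismatches) | 0, 1, 2 | robustness levels reported |
| identity cutoffs | 1.00–0.95 | resolution clustering range |
| Tm model | unified NN, 50 mM Na⁺, 0.25 µM | `DNA_NN3` |
| dimer run / hairpin | 8 bp / stem 4 + loop 3 | screen thresholds |

Problem sizes used by the test suite and acceptance script (a 91 × 802
recovery fixture, 300 random profiles, 80 × 80 oracle cross-checks, 31
segments for resolution) were chosen as the smallest scales at which
every planted structure is unambiguous; all scale linearly or
quadratically if users want larger runs.

## Known limitations

* Entropy ignores covariation and secondary structure; a column pair
  that co-varies to preserve pairing looks twice as variable as it is.
* Greedy extension can miss a better primer reachable only through a
  temporarily worse step; the exhaustive both-flank mode is practical
  only on small references.
* Hamming-only matching misses primer sites disrupted by indels, and
  complement-run screens are cruder than ΔG folding.
* Identity under the declared alignment convention can differ by a few
  hundredths from other tools' definitions on gappy pairs.
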