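# Methods

## Detection model

The detector re-implements whole-genome assembly comparison (WGAC): a
genome is compared against itself after removal of annotated repeats, and
candidate duplications are restored to full coordinates and re-scored on
the unmasked sequence.  The underlying assumptions are the classical
ones: duplicated segments retain enough unique (non-repeat) sequence to
seed an alignment; identity between copies decays by point substitution
(and small indels) so a ≥ 75% identity floor bounds the detectable age;
and repeats must be excluded *before* self-alignment because their copy
number would otherwise dominate the hit list, but included *after* for
honest length and identity statistics.

### Stages and parameters

| stage | parameter | default | why |
| --- | --- | --- | --- |
| repeat selection | max divergence | 15% | only young, alignment-confounding repeat copies are excised; older ones no longer seed spurious hits |
| masking | N-run length | 20 bp | scaffold gaps are excised like repeats; alignment across a gap is meaningless |
| seeding | k | 14 | ~1 expected random hit per 4^14 ≈ 2.7 × 10^8 position pairs; dense enough to survive 15% divergence (clean-k-mer rate 0.85^14 ≈ 0.10 per position) |
| chaining | max gap | 1000 bp | inter-seed gaps up to 1 kb are bridged, the classical "reduced gap-extension" setting |
| scoring | match/mismatch/open/extend | +1/−2/−5/−1 | a gapless 1 kb alignment at 75% identity scores exactly 250 |
| score floor | min_score | 250 | replaces a BLAST e-value cutoff with the sensitivity floor it was meant to guarantee; exposed in config |
| extension | x-drop | 20 | un-gapped end extension stops after a 20-point drop from the running best |
| refinement | band | 32 (auto-widened by the length difference) | covers small indels between copies; refinement cap 200 kb per side bounds the quadratic DP, longer pairs are skipped with a warning |
| SD filter | length, identity | > 1000 bp (strict, shorter side), ≥ 75% | "longer than 1 kb" is read strictly; ≥ 75.0 makes the 75–80 bin closed at its lower edge |

### Identity definition and terminal trimming

Identity is `100 · matches / aligned_columns` with internal gap columns in
the denominator.  The refinement alignment is global, but its path is
trimmed at both ends to the maximal-scoring contiguous subpath (a Kadane
scan over per-column scores).  This subsumes ordinary terminal-gap
trimming and also discards junk dragged in by a chance seed: a stray
k-mer hit near a true duplication can otherwise extend the chain over
hundreds of bases of non-homologous sequence, and — worse — a few
chance-matched bases crossing an excision boundary would re-include an
entire excised repeat on liftover.  Two guards address this: interval
ends whose kept-block anchor is shorter than 25 bp are dropped before
liftover, and refined intervals are shrunk by whatever the trimmed path
did not use.  On planted substitution-only duplications these choices
keep boundary errors within a few bases and refined identity within
~0.6 percentage points of the direct-comparison truth; trimming terminal
mismatch runs biases identity upward by well under the 1-point tolerance
the tests assert.

Ties in the DP break deterministically: diagonal over gap-in-a over
gap-in-b, and gap extension over opening at equal score.  The test-suite
oracle (an independently written full-matrix Gotoh) follows the same
convention, so (matches, identity) are comparable exactly; the optimal
*score* is additionally cross-checked against Biopython's
`PairwiseAligner`.

## Shared/unique classification

Presence of an SD in another species is deliberately *not* "its sequence
aligns somewhere there".  Closely related genomes share an alignable
ortholog of nearly every locus, so that reading would mark every SD
shared.  What the comparison actually asks is whether the *duplication*
exists in the other genome; operationally, the SD's two sides
(repeat-hard-masked, so a mobile element inside the SD cannot fake
presence by hitting its own family members) are searched against the
other genome, qualifying hits are clustered (components within 1 kb
joined), and a cluster counts as a locus when its repeat-inclusive span
reaches 1 kb with at least 500 aligned bp at ≥ 75% identity — the same
floor, measured the same repeat-inclusive way, as the SD definition
itself.  Two or more distinct loci mean the duplication is present.
Thresholds are configurable (`HitParams`).

Presence patterns map to groups via a table keyed by the *absent* species
set, derived from the tree: nothing absent → A (candidate ancestral
events); a whole two-species clade absent → B (deeper clade) or E
(shallower clade); single losses within those clades → C and D; patterns
present in one species only → "unique"; anything else → "other".  The
table is user-replaceable since loss-pattern taxonomies are a reporting
convention, not a property of the data.

Shared-vs-unique contrasts use Welch's t-test on identity (unequal group
variances are an empirical finding, not an assumption) and a two-sided
variance-ratio F-test; both are convention choices exposed to the user.

## TE enrichment

Content fractions are computed for three region sets — the SD union,
2.5 kb flanks (clipped, SD bases excluded, merged), and the genome — per
repeat class (DNA, SINE, LTR, LINE).  Enrichment is reported against two
denominators: the genome average (the compatibility mode matching how
published ratios in this literature reproduce from their printed
fractions) and the non-duplicated remainder (the stricter "unique
sequence" reading); both appear in the output table.  Significance uses a
placement permutation: length-matched intervals are re-placed uniformly
(sequence chosen proportional to length) n times, default n = 1000, and
p = (1 + #{null ≥ observed}) / (n + 1).  What is randomized is the SD
placement, not the repeats — the natural null for "are SDs where the
repeats are?".  A prefix-sum coverage index makes each placement O(1), so
calibration at hundreds of replicates is cheap; under a uniform null the
type-I error sits in the binomial band around 5%.

## Gene content, GO, expression, methylation

Genes belong to the SD set on ≥ 1 bp of gene-body overlap with the SD
union (configurable); a gene touching both shared and unique SDs is
"shared".  GO enrichment tests each term's 2×2 table with a one-sided
(greater) Fisher's exact test against the all-annotated-genes background,
reporting expected counts; raw p-values are flagged at α = 0.05 with
optional Benjamini–Hochberg.  Expression contrasts run per condition on
log10(RPKM + 0.01) — the pseudocount makes the transform total — with
Welch's t-test and Bonferroni factor equal to the number of conditions
tested.  Methylation uses the same contrast; an SD group with all-zero
methylation is reported as a finding, not tested.

## The synthetic-data generator

The generator emulates the statistical structure the analyses assume,
with defaults chosen as the study conditions: five species on
`(Pxyl,((Dple,Hmel),(Msex,Bmor)))`, 1 Mb genomes, 100 duplication events
(20 ancestral / 40 clade-shared / 40 lineage-unique) of 1–5 kb at 0–15%
divergence, four TE classes at 2+1+1+2% of the genome with a 3× flank
bias, 300 genes with 20% forced into duplications, 0.5× expression
suppression of SD genes over six conditions, and zero methylation in SD
gene bodies.  One ancestral sequence receives TEs and duplication *slots*
at homologous coordinates; species sequences derive from it by 0.5%
substitutions per branch; each event's copy is planted per species (so
lineage-specific events exist only in their clade) by mutating that
species' own source segment at the event's divergence.  Copies of TEs
interior to a source are annotated in the copy as well, so
masking-by-annotation stays unambiguous.  Optional small indels
(geometric, mean 2 bp) exercise the gapped-alignment path.

What it does **not** emulate — and hence what green tests do not certify
about real data: inversions and translocations, tandem-array structure,
nested/fragmented repeats with realistic age structure, assembly errors
and collapsed duplications, GC and mutation-rate heterogeneity, and
lineage-specific TE families.  Recovery rates on this generator are an
upper bound on real-assembly behaviour.

Determinism: one `numpy` Generator seeded from the config drives every
draw in a fixed order, so equal configs give byte-identical files; the
pipeline derives per-stage substreams from its own seed and writes no
timestamps into report files, making whole runs byte-reproducible.

## Problem sizes used in the checks

The shipped verification runs use a 1 Mb single-species genome with 100
planted duplications for recovery and identity accuracy; a 250 kb
five-species scenario (6 ancestral, 12 clade-shared, 10 unique events)
for shared/group agreement; 50 random pairs up to 5 kb for the alignment
oracle; 100 random genomes up to 10 kb for exhaustive coordinate
round-trips; 200 replicates at 500 placement samples for permutation
calibration; and 1000 genes (150 in SDs) over six conditions for the
expression contrast.  These sizes make the full suite complete in a few
minutes on one CPU while keeping every estimate's Monte-Carlo error well
inside the asserted tolerances.

## Known limitations

- The seed-chain-extend engine is greedy; interleaved chains on nearby
  diagonals within one bucket can fragment, which costs a little
  sensitivity for heavily nested duplications.
- Events whose unique (non-repeat) sequence falls below the score floor
  are undetectable by construction — on the default simulation this is
  the dominant (rare) failure mode, mirroring real WGAC behaviour.
- Cross-species presence requires two detectable loci; duplications whose
  copies have diverged past ~2× the event divergence plus branch
  divergence are conservatively called absent.
- The refinement cap (200 kb per side) silently bounds very large SDs;
  skipped pairs are logged.
- Fisher p-values are exact per term but the default output is
  uncorrected, matching the raw-p reporting convention of the census
  literature it mirrors; enable Benjamini–Hochberg for discovery use.
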