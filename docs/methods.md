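# Methods

This note records the models, parameter choices and numerical conventions
behind `ltrcensus`, and what the synthetic benchmark does and does not
establish about real genomes.

## The synthetic genome model

A simulated genome is an i.i.d. background sequence (default 1 Mb, GC 0.48 —
a typical fungal composition; real fungal genomes are of course not i.i.d.,
which makes the background the *hardest* case for detector specificity and
an easy case for repeat-free detection) into which element copies are
implanted one at a time.

**Element templates.** A template is one retrotransposon lineage: an LTR
(100–600 nt, default 300, with canonical 5'-TG...CA-3' termini unless
disabled), and a stop-codon-free internal region (default ~4.5 knt) encoding
GAG and the pol domains in superfamily order — GAG-AP-INT-RT-RH for
Ty1/Copia, GAG-AP-RT-RH-INT(-CHROMO) for Ty3/Gypsy. Domain protein
sequences are sampled consensi of the packaged seed families (below),
back-translated with uniform synonymous codon choice; inter-domain linkers
are random non-stop codons.

**Seed families (`ltrcensus.seedbank`).** Real pipelines build their
profiles from curated seed alignments; this package ships a deterministic
synthetic bank instead: one ancestral protein per domain family, split into
two superfamily branches (15% divergence from the ancestor each, so the
branches sit ~28% apart), with four seed sequences per branch at 8%
divergence. The branch split models the ancient Copia/Gypsy divergence and
is what makes even the domains scored by a single shared profile (Gag,
integrase core, RNase H) separate into superfamily clans in the similarity
graph — without it the synthetic cross-superfamily RH divergence is
unrealistically shallow and the two clans can merge. Profiles are built
from all eight seeds, so both branches remain detectable. Everything in the
bank is synthetic stand-in data, including the Bel/Pao-like outgroup
sequences used for tree rooting.

**Degradation.** Each copy receives Binomial(L, `point_rate`) substitutions;
with probability `stop_bias` a substitution falling in a codon is redirected
within that codon to create TAA/TAG/TGA when a single change suffices — a
deliberately crude stand-in for RIP-like inactivation (real RIP is a
dinucleotide-context C→T process; out of scope). Indels (1–3 nt, rate per
site), 5'/3' truncation (keep 30–70%), collapse to a solo LTR, and nesting
inside a previously implanted copy (depth capped at 2) are independent
per-copy events. Non-truncated insertions are flanked by a target-site
duplication (4–6 nt, default 5). Ground-truth spans cover the element
proper; the TSD is host sequence, so the genome-length gain per insertion is
span + one TSD copy (`simulate.expected_genome_gain` makes the conservation
check exact). `domain_rate_multipliers` scales the substitution rate inside
named domains; the default doubles the protease rate, reflecting the
protease being the fastest-evolving pol domain.

Defaults model the benchmark's baseline condition (intact elements:
all degradation probabilities zero); `DegradationParams.realistic()` gives a
remnant-dominated population. No quantitative degradation spectrum is
published for fungal genomes at large, so those preset values are free
parameters, not calibrated estimates.

## Detection

The detector is a seed-and-extend direct-repeat finder. Exact k-mer seeds
(default k=20) whose separation is compatible with an element length are
chained per diagonal and extended outwards ungapped with match +1 /
mismatch −2 and X-drop 12. Boundaries are then snapped to the joint LTR
signature: among nearby offsets where *both* repeat copies begin with TG
and end with CA, the combination whose implied element span is flanked by
an exact TSD is preferred (ties to the smallest trim). This pins boundaries
even when the extension overran into coincidentally matching flank
sequence. Candidates failing LTR length (100–700 nt), repeat identity
(≥0.8), or element length (1–12 knt) bounds are dropped; identity is
computed over aligned columns excluding N, and N runs longer than the seed
word break seeding.

Tandem insertions of one family generate spurious candidates (the 3' LTR of
copy *i* paired with the 5' LTR of copy *j*) that pass every filter. Any two
candidates claiming the same LTR occurrence conflict, and each conflict
component is resolved by exact maximum-total-score independent set (ties:
more candidates, then TSD-flanked, leftmost). A greedy best-first rule is
not sufficient: the spurious inter-copy pair can tie or beat each true
candidate's score and would then block *both* neighbours; maximizing total
score selects the two true elements instead. Components are one tandem
cluster each, so exhaustive enumeration is cheap (a greedy fallback guards
pathologically dense clusters).

Merging follows the 80% rule: while any two records overlap by more than
the threshold fraction of the shorter one, collapse the worst-overlapping
pair (ties by leftmost start), keeping the longest member, which inherits
the removed member's predictor labels. Keep-longest (rather than span
union) was chosen so nested elements are not fused into chimeras. External
BED/GFF3 candidate sets enter the same merge.

## Domain scanning and classification

Elements are translated in six frames (stops retained as `*`). Each profile
is a per-column log-odds matrix (base 2, additive pseudocount 0.5 over
Robinson–Robinson background frequencies; columns with ≥50% gaps dropped).
Scanning is a gapless sliding window — adequate here because synthetic
domains are not internally gapped; it is a documented simplification
relative to profile-HMM Forward/Viterbi scoring. A `*` inside a window
scores −8 per occurrence (a stop degrades but does not automatically
disqualify a domain), unknown residues score 0. Per frame and profile,
windows at or above threshold are reported after greedy best-score-first
non-overlap resolution.

Thresholds come from an empirical null: 2000 background-sampled windows per
profile, threshold = max(null mean + 8 SD, 0.3 × maximum attainable score).
The floor keeps short profiles specific on genome-scale scans; the
calibration property (≤1% of 1000 shuffled decoys above threshold, no hits
on random Mb-scale sequence) is asserted in the tests.

Classification: RVT_1/RVP_2 hits vote Gypsy, RVT_2/RVP vote Copia;
RVT_thumb and RVT_connect corroborate RT presence but never vote. Majority
wins; ties (and vote-free elements) fall back to domain order — integrase
after RNase H ⇒ Gypsy, integrase before RT ⇒ Copia; otherwise unclassified.
Chromoviral means a chromodomain hit on a Gypsy element. Functional means
≥1 hit among Gag/INT/RT/AP/RH. An element carrying both superfamilies'
RT/AP hits is flagged a complex locus and excluded from winner selection.

## Families and the most successful element

`global_identity` is matching columns of a global alignment (match +1,
mismatch −1, gap open −5, extend −1; Biopython's `PairwiseAligner` underneath)
divided by the shorter sequence's length — the cd-hit-est convention, adopted
because the published analyses used cd-hit-est at 80%. Clustering is greedy
incremental: elements longest-first, each joining the first family whose
representative (the founding, longest member) it matches at ≥ threshold,
with both orientations tried and a shared-k-mer prefilter (k=10, ≥2% of the
shorter sequence's k-mers) skipping hopeless comparisons. Star clusters
(member-to-representative identity only), as in CD-HIT. Full element
sequences, LTRs included, are clustered.

The most successful element is chosen from the largest family with ≥2
members (ties: larger total nt, then lexicographic family id), walking
members longest-first and taking the first whose pol-domain hits lie in one
reading frame and which is not a complex locus; genomes with only
singleton families yield none.

## Phylogeny

Maximum-likelihood inference is deliberately replaced by a deterministic,
classically verifiable chain: progressive alignment (average-linkage guide
tree on 3-mer distances; profile–profile Needleman–Wunsch/Gotoh with
BLOSUM62, gap open −11 / extend −1, matching the pairwise-oracle scores
exactly in the two-sequence case), TrimAl-style gap-fraction column
trimming (default ceiling 0.5 — the trimming settings of the original
analyses are not published, so this is a package choice), block
concatenation in RT-INT-RH-AP order with all-gap filler for missing taxa,
pairwise-deletion p-distances with Poisson correction −ln(1−p) capped at
3.0 for p ≥ 0.95, and Saitou–Nei neighbor joining with lowest-index
tie-breaking and branch lengths clamped at zero. NJ recovers any additive
matrix exactly (topology and path lengths), which the tests assert on
random trees; rooting bisects the branch separating the outgroup, with a
warning and best-separating-branch fallback for non-monophyletic outgroups.

The similarity-graph stand-in for force-directed clustering computes
connected components over pairwise global alignment scores; the 2D layout
itself is out of scope.

## The two structure experiments

**Superfamily components** (`pipeline.superfamily_component_experiment`):
six copies each of one Copia and one Gypsy template at 2% nucleotide
divergence; RT and RH domain proteins are extracted from scan hits and the
component threshold is set at 0.78 of the median self-alignment score — a
normalized-score operating point calibrated once against the observed
within- vs across-superfamily score bands (≥0.81 vs ≤0.76 of self-score
across template draws) and then frozen. Both domain sets split into exactly
two superfamily components.

**Domain co-inheritance** (`pipeline.domain_coinheritance_experiment`):
a population of one Gypsy template's copies with per-copy ages U(0.3, 1)
scaling a 0.10/site substitution rate, and the protease elevated ×25 so
that *every* copy's AP is mutated to saturation. RT and RH then share the
age signal (Mantel r of their distance matrices high) while the saturated
protease decouples (RT–AP r near zero). The saturating condition is
essential and is the package's operationalization of "RT and RH cluster
almost identically, the protease does not": at mild elevation a faster
protease actually carries *more* age signal per column and the contrast
reverses. The condition was fixed after a 30-seed robustness sweep
(0/30 inversions, minimum margin 0.40).

## Census statistics

Census rows enforce the count invariants (functional ≤ total; superfamily
breakdown sums to total when reported; chromoviral ≤ Gypsy); offending rows
of a loaded table are quarantined with reasons, never silently dropped.
Group aggregation uses the arithmetic mean and the midpoint-convention
median (the published analyses do not state their even-n convention). The
packaged `BASIDIOMYCOTA_FUNCTIONAL_COUNTS` — the complete set of published
functional-element counts for the eight Basidiomycota genomes — serves as a
worked aggregation group; recomputation gives mean 606.5 / median 277.5,
matching the reported 607/278 at printed rounding.

## Benchmark sizes and what passing shows

The acceptance benchmark uses ten 1 Mb genomes × 20 intact elements for
detection and classification recovery (plus ten element-free 1 Mb random
genomes for specificity), 30-copy populations at substitution rates
{0, 0.02, 0.05, 0.10} for the degradation response, 2/5/10-template
simulations for family-count recovery, 100 random interval sets and 50
random additive matrices for the combinatorial oracles. These sizes keep a
full run in a few minutes on one core.

Passing on synthetic data shows the machinery is correct under the stated
generative model. It does not show field performance: real fungal genomes
have non-i.i.d. composition, segmental duplications and tandem repeats that
stress detector specificity; real domains diverge with indels that a
gapless PSSM scan handles worse than profile HMMs; real LTR boundaries blur
under post-insertion degradation. The detector's 100% recall/specificity is
therefore a correctness statement about intact elements on random
background, not a benchmark against LTRharvest-class tools on real
assemblies.

## Known limitations

- Gapless domain scanning; no frameshift-aware DP (frame-split domains are
  still found per frame, and winner selection requires single-frame pol).
- No PBS/PPT detection, LTR divergence dating, or cross-contig element
  reconstruction.
- RIP is modeled as stop-biased point mutation, not a dinucleotide-context
  process.
- The identity denominator (shorter sequence) makes a truncated fragment
  cluster with its parent family — intended, as cd-hit-est behaves the same.
- Census means/medians over genomes with zero elements follow whatever rows
  the table provides; both including and excluding such genomes are
  legitimate summaries and the aggregation makes no hidden choice.
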