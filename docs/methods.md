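# Methods

This note documents the models, conventions and numerical choices behind
the package, and what the synthetic fixtures do and do not establish.

## Coordinates and target geometry

All intervals are 0-based half-open. A target's `cut_coord` is the boundary
index of the blunt SpCas9 cut, placed 3 bp 5′ of the NGG PAM (between
protospacer bases 17 and 18) — the canonical SpCas9 cleavage geometry. With
boundary-index cuts, the inter-DSB distance of a guide pair is exactly
`|cut_a − cut_b|` bp, which makes the divisible-by-3 test in pair scoring
unambiguous. The 30-nt context window is 4 nt upstream of the protospacer,
the 20-nt protospacer, and 6 nt downstream (the PAM being the first 3 of
those 6); the cut boundary sits at context offset 21. Sites whose window
would run off the sequence, or whose window contains an ambiguous base, are
skipped — including sites at splice junctions, since a context must be one
contiguous genomic window. Only N is accepted as a wildcard in PAM
patterns; other IUPAC codes are rejected rather than silently matched.

For coding annotation, the codon "containing" a cut is the codon of the
first base 3′ of the cut along the transcript orientation (the base at
`cut_coord` on plus-strand transcripts, at `cut_coord − 1` on minus-strand
ones). When several transcripts overlap the cut, the first CDS containing
it supplies the amino-acid index.

## Potency model

Features are position-specific 3-mer identities: position *i* of the
context contributes the 3-mer at offsets [i, i+3), i = 0..27, one-hot
encoded as 28 × 64 columns. A position-free bag-of-3-mers codec is
available as a comparison switch but is not the default, because the
positional reading is what gives the forests access to PAM-proximal
structure.

Labels are within-gene midpoint percentiles of raw efficacy: ≥ 60 potent,
≤ 40 weak, the middle 20% discarded; genes with fewer than three guides are
dropped with a warning. Percentiles are computed per gene by default for
both data sources (a global-percentile switch exists, since mutation-rate
assays arguably support global ranking).

Each ladder trains ten scikit-learn random forests identical in features,
labels and seed derivation, differing only in the class-weight matrix: the
rung-*k* forest weighs the weak class by penalty *k* from the ladder
(0.2, 0.4, …, 2.0), making a false positive (weak called potent) *k* times
as costly as a false negative. No resampling is used; the cost matrix alone
handles asymmetry. Prediction is the forest's default majority vote under
those weights. The per-ladder score is the **maximum** rung index calling
potent — no monotone closure is imposed across the ladder, so a guide can
in principle fail rung 3 and pass rung 4; the score is still 4 (or higher).
The combined score is the minimum over the two ladders. Out-of-bag scores
use each forest's OOB decision function, so a training guide is only scored
by trees that never saw it.

Defaults: 1000 trees per forest, `rng_seed` 17 (rung *k* uses seed + *k*),
recorded in the serialized bundle's manifest together with the penalty
ladder and feature-codec version. Serialization is joblib; round-trips are
bit-stable for scoring.

## Repair model and FSM test

Microhomology enumeration reports every maximal exact repeat with one copy
ending at or before the cut and one beginning at or after it, both copies
within a search window of the cut. Sub-repeats of a longer repeat at the
same locus pair are suppressed by requiring left-maximality (the bases
immediately before both copies differ) and greedy right extension; distinct
annealing registers of a homopolymer still appear as distinct pairs, which
is the desired biology. Defaults: minimum homology length 2 nt, window
30 nt per side — values in line with published MMEJ deletion analyses; both
configurable.

The resolution model is an OLS fit of observed frequency on (length, GC
fraction, distance) plus intercept, on raw frequencies (no link function or
log transform; the alternative log-frequency fit is a caller-side
transform). The distance covariate of a pair is the **sum** of its two
flank distances, matching a single-scalar "distance to the break" reading;
a min-distance switch exists. Predictions are clamped at 0 before
normalization, since likelihoods cannot be negative.

`deletion_length = dist_upstream + dist_downstream + length` (the
intervening segment plus one repeat copy). FSM likelihood is the clamped
predicted mass on deletions with length not divisible by 3, over the total
mass; it is undefined (test failed) when the total is 0. The test passes
only when the likelihood strictly exceeds the 0.66 threshold **and** the
unnormalized sum reaches the HEJ cutoff — the median of likelihood sums
over a background of coding cut sites, supplied by the caller (the package
does not bundle a genome). Blunt-NHEJ outcomes are deliberately outside the
fraction: the model covers homology-guided resolutions only, and sites
where those are implausible simply fail the test rather than falling back
to an NHEJ model.

## Conservation

Profiles are consumed, never computed: a TSV of per-residue deleteriousness
values in the PROVEAN sign convention. The score is the windowed mean
absolute value over ±2 residues around the cut codon (window truncated at
protein ends; flank configurable). This windowed-mean form is a
reconstruction of the published per-site aggregation, whose exact formula
is not public. Non-coding cuts score as undefined and fail the test instead
of erroring the pipeline. The pass threshold is the strict median of a
background score collection, so at most half of any background passes
against its own median.

## Consolidated score and slates

Score 0 → excluded; bands 1–3 / 4–6 / 7–10 → groups A / B / C. The top band
absorbs 10 so the three groups partition 1–10; bands are configurable and
validated (disjoint, covering). `croatan_score = 3·group + passes + 1` is a
bijection from the 9 (group, passes) states onto 1..9; the two tests are
deliberately symmetric (a count, not a weighted pair). Slates sort by
consolidated score, then forest score, then 5′-most cut in the transcript
(a tie-break reflecting the N-terminal bias of effective cuts), then site
id, making output invariant to input order.

## Pairing

Off-target risk defaults to the count of exact genomic occurrences of the
12-nt 3′-proximal seed followed by NGG, excluding the guide's own site; the
scorer is a pluggable callable for anything more refined. Pair scoring
applies, in order: overlap → final 0 (terminal, no increments); base 2.5
iff distance < 10 kb, distance ≢ 0 (mod 3), and the transcript-id sets of
the two cuts intersect ("common isoform" operationalized as shared
transcript); +1 iff one score < 7 and the other > 7 (a guide at exactly 7
never forms an imbalanced pair). Pairs failing the base conditions but not
overlapping still earn the +1 when applicable. No separate same-exon bonus
is implemented: its increment value is not recoverable, and shared
transcripts subsume the intent.

Matching uses the networkx blossom implementation (maximum weight, not
merely maximal); output pairs are canonicalized and sorted for determinism.
With non-negative weights the optimum over all matchings equals the optimum
over perfect matchings, which is what the brute-force test oracle
enumerates (945 perfect matchings at n = 10). Construct assembly puts the
higher-scoring guide at hU6 (lexicographic on ties) and draws barcodes with
a minimum pairwise Hamming distance of 3 (length 12, seeded RNG or caller
pool). Combinatorial mode enumerates all ordered (hU6, cU6) pairs including
self-pairs — 100 guides → 10,000 constructs; heuristic scores are
meaningful only within a gene, so cross-gene pairs carry caller-chosen
weights.

## Screen analysis

Normalization is counts-per-million per sample before the ratio, with
pseudocount 1 (both configurable). LFC is computed per replicate, then
averaged; z-scores are standardized per replicate by default (stratum
configurable to whole-screen; the choice is recorded in the result config).
Gene percentiles use midpoint ranks with ties averaged, oriented so the
most-depleted guide has the highest depletion percentile. Statistical
comparisons use rank-sum (2 groups), Friedman (matched k groups) or
Kruskal–Wallis, plus Spearman association; p-values are reported raw, with
any multiple-testing correction left to the caller since hit calling never
gates on them. Hit calling flags the q% most-depleted constructs
(q ∈ {10..50} by default) and requires ≥ 2 flagged constructs per gene;
TPR/FPR are computed over labelled essential/non-essential genes only,
while unlabelled genes are still called.

## Scar analysis

Only CIGAR I/D operations count as edits; M-op mismatches and soft clips
are ignored. Mate edit lists are merged per fragment; a fragment whose
mates disagree about an edit that both aligned spans should contain is
flagged discordant and excluded (conservative counting). Classification
attributes indels to a cut if they touch its ±5 nt window (no window is
published; ±5 keeps 1–4 nt indels at the cut attributable without bridging
the two sites). A deletion touching both windows is a fragment deletion,
subclassified DSB–DSB only when its endpoints equal the two cut boundaries
exactly and no other edit exists on the fragment. Edits outside both
windows never change the class but are counted in a diagnostics field.
Rates are per fragment (read pair), not per read; multi-sample mode
averages class rates across samples.

## Synthetic fixtures

The generators are pure functions of their configs; every run is
reproducible from the seed and emits a ground-truth sidecar.

* **Genome**: two-exon genes on alternating strands, CDS from sense codons
  plus a terminal stop (so translations are internally stop-free), ~80 nt
  introns, non-overlapping genes, with resampling until each gene clears a
  20-NGG-site floor. This emulates gene structure, not base composition or
  repeat content of a real genome.
* **Efficacy**: potency = 3.0 × protospacer GC fraction + 2.0 × presence of
  a planted 3-mer at context offset 12 (planted with probability 0.5) +
  gaussian noise (σ = 0.5), giving the forests positional signal that
  explains > 50% of variance. Default 40 genes × 10 guides.
* **Repair table**: frequencies from the linear truth (intercept 0.1,
  length 0.05, GC 0.3, distance −0.01; σ = 0.01, n = 500), covariates drawn
  over realistic ranges; degenerate covariate ranges are rejected because
  they would produce a rank-deficient design.
* **Screen**: reference abundances lognormal (σ = 0.3); depletion is
  planted on the **normalized** scale: affected constructs get expected CPM
  log-ratio exactly δ (default −2, i.e. 4-fold), and the null constructs
  absorb the complementary composition shift dictated by the normalization
  identity Σ pᵢ·2^LFCᵢ = 1 — exactly the bias a real pooled screen shows
  under CPM normalization. Counts are gamma-Poisson (dispersion 0.05) at
  1000× per-construct depth, in 3 replicates. Dual libraries plant δ for
  one essential guide and 1.5 δ when both guides hit the same essential
  gene.
* **Scars**: default mixture 10% no-edit, 20%/20% single-cut indels, 10%
  dual, 30% exact DSB–DSB deletion, 10% extended deletion; 150-nt mates on
  a 300-nt amplicon with cuts at 100/200. CIGARs are constructed to be
  internally consistent; no sequencing error or alignment noise is
  simulated, so classifier agreement on these fixtures demonstrates
  correctness of the CIGAR logic, not robustness to mapper artifacts.

Because the fixtures are noise-controlled and self-consistent, passing
tests show the algorithms recover what was planted under the stated noise
models; they do not certify performance on real screens, where guide
efficacy, repair outcome and count dispersion have heavier tails.

## Problem sizes and determinism

The test and acceptance runs train ladders at 30–60 trees per forest on
400-guide fixtures, enumerate 945 perfect matchings for the matching
oracle, and use 2000-fragment scar mixtures and 200-construct screens —
sizes chosen so the planted effects are comfortably detectable while the
whole suite stays quick; the package defaults (1000 trees) remain the
production setting. All stochastic tests fix their generator seeds;
hypothesis-based property tests run derandomized.

## Known limitations

Only NGG Cas variants are supported. The potency ladders must be trained by
the user on real efficacy tables to reproduce published guide rankings —
the original training data are not bundled, so absolute scores on real
genomes depend on the caller's data. The off-target default is a seed-count
heuristic, not an alignment-based scorer. The repair model is linear on raw
frequencies; likelihoods are relative weights, not probabilities. Scar
classification trusts the mapper's alignments and performs no indel
realignment.
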