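# croatan

Design and analysis toolkit for single and dual-sgRNA CRISPR knockout
libraries.

Pooled CRISPR knockout screens live or die by guide quality: a weak sgRNA, a
cut whose repair scar stays in frame, or a cut in a dispensable stretch of
protein all blunt the phenotype. This package implements a consolidated
guide-selection and screen-analysis framework for SpCas9 (NGG) knockout
reagents, aimed at people who design pooled or arrayed knockout libraries
and analyze their depletion screens.

## What it computes

**Potency (stringency-laddered random forests).** Each 30-nt target context
(4 nt upstream + 20-nt protospacer + PAM-containing 6 nt downstream) is
decomposed into its 28 overlapping positional 3-mers. Two ensembles of ten
random forests (1000 trees each by default) are trained on efficacy tables
from two independent assay types, with guides labelled potent/weak by a
top/bottom-40% within-gene percentile cutoff. The ten forests of a ladder
share everything except an incrementally increasing penalty for
false-positive calls (0.2, 0.4, ..., 2.0), so rung *k* is stricter than
rung *k−1*. A guide's per-ladder score is the highest rung that calls it
potent; its combined forest score is

```
forest_score = min(score_ladder1, score_ladder2)   ∈ {0..10}
```

— the highest stringency level passed in *both* data sources.

**Frameshift likelihood (microhomology repair model).** Cas9 breaks are
partly resolved by microhomology-guided end joining. All maximal exact
repeats flanking the cut are enumerated; each candidate resolution's
likelihood is a linear function of repeat length, GC fraction and distance
to the break (OLS-fitted on observed resolution frequencies, clamped at 0).
The FSM likelihood is the fraction of predicted likelihood mass on
deletions with length ≢ 0 (mod 3). A guide passes the FSM test when this
fraction strictly exceeds 0.66 **and** its total homology-repair likelihood
clears a background-median cutoff (homology repair must be plausible at all).

**Conservation.** The cut's codon neighbourhood is scored as the windowed
mean |PROVEAN-style deleteriousness| (±2 residues); a guide passes when its
score strictly exceeds the median over background coding cut sites.

**Consolidated 1–9 score.** Forest score 0 excludes a guide; scores 1–3,
4–6 and 7–10 map to groups A, B, C. Within a group the guide earns one
point per test passed (conservation, FSM):

```
croatan_score = 3·group + tests_passed + 1   ∈ {1..9}
```

**Dual-guide pairing.** Per gene, the top-20 guides are reranked by
off-target risk (exact 12-nt seed + NGG genomic matches), the top 10
scored pairwise — 0 for overlapping targets (terminal); 2.5 base when cuts
are < 10 kb apart, their separation is not divisible by 3, and they share a
transcript; +1 when scores are imbalanced (one < 7, one > 7) — and five
constructs are chosen by maximum weight matching (blossom). The
higher-scoring guide takes the human-U6 slot; a Hamming-separated barcode
identifies each pair.

**Screen analysis.** Count tables are filtered (reference count ≥ 50),
converted to per-replicate CPM log2 ratios with a pseudocount, z-scored
and percentile-ranked within gene; group comparisons use rank-sum /
Friedman / Spearman statistics; gene hits require ≥ 2 constructs in the
most-depleted q% at stringencies 10–50%.

**Scar analysis.** Read pairs mapped to a two-cut amplicon are classified
from their CIGAR strings into no-edit, single-cut indels, dual indels and
fragment deletions, the latter subclassified as exact DSB–DSB re-ligation
or not.

A deterministic synthetic-fixture module (`croatan.simulate`) generates
every input format with planted ground truth, so the whole pipeline is
testable offline.

## Worked example

`python examples/05_screen_analysis.py` simulates a 200-construct screen
(20 essential + 20 non-essential genes, 5 guides each, 3 replicates,
essential constructs planted at LFC −2) and analyzes it:

```
constructs passing the 50-read reference filter: 200/200
mean LFC essential:     -1.97  (planted -2.0)
mean LFC non-essential: +0.82
stringency  TPR   FPR
    10%    0.25  0.00
    20%    0.60  0.00
    30%    0.95  0.00
    40%    1.00  0.00
    50%    1.00  0.00
```

The essential-construct mean recovers the planted depletion; non-essential
constructs appear slightly enriched because CPM renormalization shifts the
remaining mass upward when half the library drops out. TPR > FPR at every
stringency shows the two-construct hit rule separates essential genes from
neutral controls. The other `examples/*.py` scripts walk through target
enumeration, potency training, frameshift likelihood, construct design and
scar classification the same way.

A `croatan` console command exposes the same pipeline for shell use
(`croatan --help`): `simulate`, `targets`, `train`, `forest-score`, `fsm`,
`conservation`, `score`, `pair`, `screen`, `scars`. Every subcommand writes
a manifest (version, resolved options, input digests, seeds) next to its
output.

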