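# Methods

## Problem and model

A type II toxin–antitoxin (TA) operon encodes two proteins whose
production ratio (antitoxin over toxin, A/T) must stay above 1 in growing
cells. Four regulatory architectures can maintain that ratio, and each
leaves a distinct fingerprint in sequence annotation and RNA-seq:

1. **Class 1 (translational).** One transcript; antitoxin and toxin mRNA
   are present at near-equal concentration (A/T coverage ratio below
   two-fold), so the ratio must be set by different translation rates.
2. **Class 2 (transcriptional + translational).** A second *external*
   promoter starts transcription close to the toxin RBS, producing a
   variant transcript with a weakened toxin RBS.
3. **Class 3 (transcript truncation).** Antitoxin mRNA clearly exceeds
   toxin mRNA without any promoter to explain it; the toxin-coding region
   is truncated by an early terminator or toxin-biased degradation,
   visible as a downward coverage step inside the toxin CDS.
4. **Class 4 (internal promoter).** A promoter inside the operon's coding
   span adds an antitoxin-only transcript, visible as an upward coverage
   step upstream of the antitoxin CDS.

The package computes the evidence layers (coverage ratios, replicate
errors, changepoints, TIR consensus) and combines them with a fixed
precedence; everything is deterministic given the inputs.

## Coordinates and annotation

All per-operon coordinates are 0-based, half-open and plus-strand
normalized: minus-strand operons are flipped on read so transcription runs
left to right, anchored so that the most upstream annotated TSS (or the
leftmost CDS if no promoter is upstream) sits at position 0. Operon
membership and toxin/antitoxin roles come from an explicit curated table,
never from proximity inference. A promoter is *internal* iff its TSS lies
strictly inside the span from first CDS start to last CDS end.

The RBS window of a gene defaults to the 20 nt upstream of its start
codon (configurable); there is no community-standard RBS extent, and 20 nt
comfortably covers Shine–Dalgarno placements in *E. coli*.

## Coverage statistics

RPKM = 10⁹·n/(L·T) with fractional counts (multi-mapped reads = 0.5).
Per-dataset A/T ratios are independent of T; a zero toxin count makes the
ratio undefined and excludes that dataset for that operon (no pseudocount
— low-coverage systems are filtered, not imputed). The across-dataset
summary is the median and the sample SD (n−1 denominator, configurable via
`ddof`). The inclusion filter is strict: an operon is dropped iff either
gene has n/L < 1 in strictly more than half of the datasets.

Replicate error is reported in two directions per condition: SE of
ln(c_A/c_T) and of ln(c_A·c_T), each sd/√m with the sample sd over the m
replicates, plus log10 versions (divided by ln 10). Conditions are pooled
per operon by averaging variances (√mean(se²)); the reference design has
near-equal replicate counts per condition, so equal condition weights are
appropriate. Both the per-condition and pooled estimates are emitted, since
either may be wanted for plotting rotated error bars.

## Changepoint detection

One breakpoint only — each class needs at most one internal feature.
The profile is transformed to ln(1+x) for variance stabilization, then an
exhaustive search over breakpoints with both segments ≥ `min_segment`
(default 50 nt) finds the SSE-optimal split in O(n) via prefix sums. The
split is reported only if (i) the two-segment Gaussian BIC beats the flat
model by `bic_threshold` (default 10; the two-segment model is charged two
extra parameters, the second mean and the breakpoint) and (ii) the
raw-coverage fold change across the split reaches `min_fold` (default 2).
The BIC is a heuristic under the Gaussian SSE approximation; the fold
gate is what keeps small-but-consistent steps (e.g. a 1.3× boundary
between genes on one transcript) from being called.

For the class-4 rule the relevant question is whether an upward step lies
*upstream of the antitoxin CDS start*. The one well-documented class-4
system has its internal promoter ~280 nt upstream of the antitoxin —
i.e. inside the upstream toxin CDS — so restricting class-4 evidence to
intergenic/leader regions would miss the defining case. The classifier
therefore accepts a significant up-step at any position before the
antitoxin CDS start (toxin CDS, intergenic or leader).

## TIR consensus

TIR calculators disagree strongly on absolute rates, so only the sign
(antitoxin TIR above/below toxin TIR) per method and transcript variant is
used, with a majority (2-of-3) rule; fewer than two usable calls, or an
even split, is "insufficient". Tied TIR values within a method carry no
sign and are rejected rather than counted as half-votes.

The built-in window scorer is a labelled **surrogate**: a log-linear score
over the −11..0 window upstream of the start codon (per-position base
weights plus the best Shine–Dalgarno hexamer term: matches to AGGAGG
weighted by `asd_weight`, with a linear penalty on deviation from
`optimal_spacing`). Its shipped coefficients are placeholders chosen only
so SD-like windows outscore SD-free ones; users supplying a fitted
coefficient file get the same machinery. It exists to exercise the
pipeline without the external calculators and never claims numeric
agreement with them.

## Classification rules

Precedence, given an included ratio summary:

1. internal promoter (annotation or up-step before the antitoxin CDS) → 4;
   if a proximal second external promoter coexists, 4 wins and the
   contradiction is recorded in the evidence trail;
2. else a second external promoter with TSS within `proximal_window`
   (default 50 nt) of the first CDS start → 2; distal extra promoters do
   not count;
3. else antitoxin excess → 3: median ratio above 2 + `borderline_delta`,
   OR median in the borderline band with a toxin-higher TIR consensus,
   OR a significant down-step inside the toxin CDS;
4. else → 1, except that a borderline median additionally requires an
   antitoxin-higher consensus (otherwise "unclassified").

`borderline_delta` = 0.25 around the two-fold cutoff is this package's
operationalization of "near the cutoff": it is the single band for which
the tie-break reproduces all published borderline placements (medians 1.89
and 1.99 to class 1 with supporting consensus; 2.08 to class 3 with an
opposing one). Protein-synthesis rates (ribosome profiling) are advisory
only: a confident (≥128 reads per gene) synthesis ratio < 1 raises
`synthesis_ratio_below_one` but never changes the class, and rates under
128 reads are low-confidence and ignored.

## Synthetic data: what it emulates and what it does not

The generator reproduces the reference study design: 13 datasets (one
condition × 3 replicates + five × 2), gene lengths typical of type II
systems (toxin 250–350 nt, antitoxin 200–300 nt), and per-class transcript
architectures. Gene counts are negative-binomial (dispersion 0.1,
variance μ + 0.1μ², the standard bulk-RNA-seq noise model at
biological-replicate scale) around coverage-integral means at a default
depth of 50 reads/base for the toxin gene, with a shared per-operon,
per-dataset lognormal factor (ln-sd 0.2) capturing the fact that both
genes ride one transcript — which is what makes the ratio-direction error
smaller than the magnitude-direction error. Base profiles are Poisson
around the architecture's expected coverage. True class-level A/T ratios
default to 1.3 / 1.0 / 2.9 / 1.0 (classes 1–4; class 4 is the
*full-operon* counted ratio, its excess antitoxin being visible in the
profile, not the gene counts). Class-4 internal promoters are deliberately
*not* annotated, so recovery must come from the coverage step.

Not emulated: positional coverage bias, mappability, batch effects,
sequence-realistic promoters/RBS motifs, read-level data. Passing the
synthetic recovery checks therefore demonstrates the pipeline's logic and
statistical behavior under the stated noise model, not performance on
arbitrary real libraries.

A note on attainable accuracy: a median over 13 ratios whose per-dataset
CV is ~40–50% (NB dispersion 0.1 in both genes) carries ~13% sampling
error — the same order as the published per-system SDs — so per-operon
ratio estimates are validated in aggregate (the mean of class-1 medians is
within a few per mill of truth at n = 50) rather than one operon at a
time.

## Problem sizes and determinism

The shipped analyses use 200 operons (50 per class) for recovery, 100
seeded runs for changepoint power, and 13-dataset designs throughout —
sizes at which every statistical claim the package makes is already
stable. All randomness flows from one `numpy.random.Generator` per
simulation; a fixed seed gives byte-identical outputs, and the file-based
pipeline is deterministic given its inputs (reports carry no timestamps).

## Known limitations

- One changepoint per operon; tandem internal features would be merged or
  the stronger one reported.
- The BIC threshold is calibrated for profiles of a few hundred to a few
  thousand bases at ≥ ~20 reads/base; very shallow profiles lose power
  (they are typically removed by the coverage filter anyway).
- The surrogate TIR scorer's coefficients are placeholders; sign-level
  fidelity on real sequences requires externally fitted coefficients or
  the external calculators themselves.
- The classifier consumes a single consensus per operon (variant "P1" by
  convention when several variants exist); variant-specific classification
  beyond the class-2 promoter rule is out of scope.
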