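# taclass — regulatory classification of type II toxin–antitoxin operons

Type II toxin–antitoxin (TA) systems are two-gene bacterial operons
encoding a stable toxin and an unstable, protease-degraded antitoxin. A
cell stays in the susceptible (non-persister) state only while the
antitoxin-to-toxin (A/T) production ratio stays well above 1, which makes
the *mechanism* that maintains that ratio — transcriptional or
translational — a central question for bacterial persistence.

`taclass` implements a rule-based classification of type II TA operons
into four regulatory classes, for microbial genomicists who have operon
annotations and bulk RNA-seq (and optionally ribosome profiling or
translation-initiation-rate predictions) for a bacterium of interest:

| Class | Mechanism | Signature |
|---|---|---|
| 1 | translational | single transcript, median A/T mRNA ratio < 2 |
| 2 | transcriptional + translational | second external promoter near the toxin RBS |
| 3 | transcript truncation | A/T > 2, or a downward coverage step in the toxin CDS |
| 4 | internal promoter | upward coverage step upstream of the antitoxin CDS |

## The statistics at the core

Coverage of a CDS with fractional read count *n* (multi-mapped reads count
0.5), length *L* and library size *T* is **RPKM = 10⁹·n/(L·T)**. For each
operon the per-dataset ratio A/T = RPKM_A/RPKM_T (the *T* cancels) is
summarized by its **median across datasets** (13 in the reference design:
one condition × 3 replicates + five conditions × 2 replicates) and its
sample SD, after an inclusion filter that drops operons with n/L < 1 in
more than half of the datasets.

Replicate uncertainty is decomposed into two orthogonal log-space
directions: the SE of **ln(c_A/c_T)** (ratio direction) and of
**ln(c_A·c_T)** (magnitude direction); the ratio-direction error is exactly
0 whenever the ratio is constant across replicates.

Transcript-structure evidence comes from a single-changepoint fit to
ln(1+coverage) (exhaustive split search, BIC margin ≥ 10, fold change ≥ 2),
and translation-initiation-rate (TIR) predictions enter only as a
**2-of-3 majority of signs** (is the antitoxin TIR above the toxin TIR?)
per transcript variant.

## Worked example

Classify the bundled ten-system *E. coli* K-12 evidence fixture (published
medians, promoter layouts, TIR sign columns):

```bash
python analysis/01_fixture_classification.py
```

prints

```
   system  class                         mechanism mrna_ratio        consensus synthesis                 anomalies
    FicAT      1                     translational         <2 antitoxin_higher        LC                      none
    ...
    HicAB      2 transcriptional_and_translational         <2     toxin_higher        LC                      none
DinJ-YafQ      3             transcript_truncation         >2     toxin_higher         +                      none
    YafNO      3             transcript_truncation         >2     toxin_higher         +                      none
    RnlAB      4                 internal_promoter         <2 antitoxin_higher         - synthesis_ratio_below_one

10/10 systems match their published class; anomalies: ['RnlAB']
```

— six systems are class 1 (translational regulation), HicAB lands in
class 2 via its second proximal external promoter, the two systems with a
greater-than-two-fold mRNA ratio land in class 3, and RnlAB's internal
promoter puts it in class 4, flagged because its (confident)
protein-synthesis-rate ratio is below 1.

A fully synthetic end-to-end run — generator → files → pipeline →
classification against known truth labels:

```bash
python analysis/03_synthetic_recovery.py
# overall recovery: 100.0% ({'1': '50/50', '2': '50/50', '3': '50/50', '4': '50/50'})
# class-1 mean of median ratios: 1.300 (truth 1.3)
# changepoints within ±10 nt: 100/100
```

The same machinery is scriptable through the `taclass` CLI
(`simulate`, `fixture`, `quantify`, `errors`, `profile`, `tir`,
`classify`, `run-all`), e.g.:

```bash
taclass simulate --out-dir scratch/demo --n-per-class 5 --seed 1
taclass classify --config scratch/demo/run_config.yaml
```

which writes `ratios.tsv`, `errors.tsv`, `changepoints.tsv`,
`consensus.tsv`, `classification.tsv` and `evidence.json` under
`scratch/demo/reports/`.

## Layout

- `src/taclass/` — the library: `operon_model`, `coverage_quant`,
  `replicate_error`, `profile_evidence`, `tir_consensus`, `classifier`,
  `synthetic_data`, `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers over the library.
- `docs/methods.md` — models, parameters, numerical choices, limitations.
- `tests/` — unit, property and acceptance tests.
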