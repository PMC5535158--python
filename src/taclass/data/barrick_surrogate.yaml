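# Surrogate log-linear coefficients for the built-in window scorer.
#
# SURROGATE: these coefficients are this package's own placeholder values,
# chosen so that Shine-Dalgarno-like windows score higher than SD-free ones.
# They are NOT the published regression coefficients of any external
# translation-initiation-rate calculator; replace this file to use a fitted
# coefficient set.  Offsets are relative to the first base of the start
# codon (offset 0); the scored window is [-11, 0].
asd_weight: 1.5          # per matching base against the SD consensus AGGAGG
optimal_spacing: 7       # nt between SD hexamer 3' end and the start codon
spacing_penalty: 0.25    # per nt of deviation from optimal_spacing
base_weights:            # per-position additive weight by base (all offsets)
  A: 0.05
  G: 0.08
  C: -0.05
  T: -0.02
position_weights: {}     # optional per-offset overrides, e.g. {-9: {G: 0.5}}
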