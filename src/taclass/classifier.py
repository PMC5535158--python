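"""Four-class decision procedure for type II TA operon regulation.

Class 1 — single transcript, antitoxin/toxin mRNA roughly equal (< 2-fold);
          differential protein production is translational.
Class 2 — a second *external* promoter starts transcription near the toxin
          RBS, yielding a variant transcript with a weakened toxin RBS:
          transcriptional and translational regulation combined.
Class 3 — antitoxin mRNA clearly exceeds toxin mRNA because the toxin-coding
          region is truncated (early terminator or toxin-biased degradation).
Class 4 — an internal promoter adds an antitoxin-only transcript.

Evidence precedence: internal-promoter evidence (annotation or an upward
coverage step upstream of the antitoxin CDS) wins, then proximal second
external promoters, then antitoxin-excess evidence (ratio above the
two-fold band, a borderline ratio broken toward the toxin by the TIR
consensus, or a downward coverage step inside the toxin CDS), else class 1.
Borderline ratios (within ``borderline_delta`` of 2.0) need the TIR
consensus to support whichever side they land on.

Protein-synthesis-rate (ribosome profiling) data is advisory only: a
confident synthesis ratio below 1 raises an anomaly flag but never changes
the class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from taclass.coverage_quant import RatioSummary
from taclass.operon_model import OperonModel
from taclass.profile_evidence import ChangepointCall
from taclass.tir_consensus import ANTITOXIN_HIGHER, TOXIN_HIGHER, ConsensusCall

LOW_CONFIDENCE_READS = 128  # ribosome-profiling reads below which rates are unreliable

MECHANISM = {
    1: "translational",
    2: "transcriptional_and_translational",
    3: "transcript_truncation",
    4: "internal_promoter",
    "unclassified": "unknown",
}


@dataclass
class SynthesisRates:
    """Protein synthesis rates (ribosome profiling) for one operon.

    Rates with fewer than 128 mapped reads on either gene are low
    confidence; ``relative_error`` is the assumed fractional error of a
    confident rate (30% by default).
    """

    operon_id: str
    rate_antitoxin: float
    rate_toxin: float
    reads_antitoxin: int
    reads_toxin: int
    relative_error: float = 0.30

    @property
    def low_confidence(self) -> bool:
        return (self.reads_antitoxin < LOW_CONFIDENCE_READS
                or self.reads_toxin < LOW_CONFIDENCE_READS)

    @property
    def ratio(self) -> float:
        return self.rate_antitoxin / self.rate_toxin


@dataclass
class ClassAssignment:
    operon_id: str
    assigned_class: int | str  # 1..4 or "unclassified"
    mechanism: str
    evidence: list[str] = field(default_factory=list)
    anomaly_flags: list[str] = field(default_factory=list)


def _pick_consensus(
    consensus_by_variant: dict[str, ConsensusCall] | None,
) -> ConsensusCall | None:
    """Primary-transcript consensus: variant 'P1' if present, else the sole one."""
    if not consensus_by_variant:
        return None
    if "P1" in consensus_by_variant:
        return consensus_by_variant["P1"]
    if len(consensus_by_variant) == 1:
        return next(iter(consensus_by_variant.values()))
    return consensus_by_variant[sorted(consensus_by_variant)[0]]


def classify(
    operon: OperonModel,
    ratio: RatioSummary,
    changepoint: ChangepointCall | None = None,
    consensus_by_variant: dict[str, ConsensusCall] | None = None,
    synthesis: SynthesisRates | None = None,
    borderline_delta: float = 0.25,
    proximal_window: int = 50,
) -> ClassAssignment:
    """Assign a regulatory class from the combined evidence for one operon.

    ``borderline_delta`` sets the band [2 - delta, 2 + delta] around the
    two-fold cutoff within which the TIR consensus breaks the tie;
    ``proximal_window`` is how close (nt) a second external TSS must be to
    the first CDS start to count as "near the toxin RBS" (class 2).
    """
    evidence: list[str] = []
    flags: list[str] = []

    def assignment(cls: int | str) -> ClassAssignment:
        if synthesis is not None and not synthesis.low_confidence and synthesis.ratio < 1:
            flags.append("synthesis_ratio_below_one")
            evidence.append(
                f"synthesis rate ratio {synthesis.ratio:.2f} < 1 with confident coverage"
            )
        return ClassAssignment(operon.operon_id, cls, MECHANISM[cls], evidence, flags)

    if not ratio.included:
        evidence.append("failed coverage inclusion filter")
        return assignment("unclassified")

    median = ratio.median_ratio
    lo_band, hi_band = 2.0 - borderline_delta, 2.0 + borderline_delta
    in_band = lo_band <= median <= hi_band
    cons = _pick_consensus(consensus_by_variant)
    verdict = cons.verdict if cons is not None else None

    # (1) internal promoter: annotation, or an up-step upstream of the antitoxin CDS
    internal = operon.internal_promoters()
    up_step = (
        changepoint is not None
        and changepoint.significant
        and changepoint.direction == "up"
        and changepoint.position < operon.antitoxin.start
    )
    if internal or up_step:
        if internal:
            evidence.append(
                "internal promoter annotated at "
                + ", ".join(str(p.tss) for p in internal)
            )
        if up_step:
            evidence.append(
                f"coverage step up at {changepoint.position} "
                f"(fold {changepoint.fold:.1f}) upstream of the antitoxin CDS"
            )
        proximal_second = _proximal_second_external(operon, proximal_window)
        if proximal_second is not None:
            evidence.append(
                "contradiction: proximal second external promoter at "
                f"{proximal_second.tss} also present; internal-promoter evidence wins"
            )
        return assignment(4)

    # (2) two external promoters with the second TSS near the first CDS start
    proximal_second = _proximal_second_external(operon, proximal_window)
    if proximal_second is not None:
        evidence.append(
            f"second external promoter TSS {proximal_second.tss} within "
            f"{proximal_window} nt of first CDS start {operon.genes[0].start}"
        )
        return assignment(2)

    # (3) antitoxin-excess evidence
    down_in_toxin = (
        changepoint is not None
        and changepoint.significant
        and changepoint.direction == "down"
        and operon.toxin.contains(changepoint.position)
    )
    if median > hi_band:
        evidence.append(f"median A/T ratio {median:.2f} above two-fold band")
        return assignment(3)
    if in_band and verdict == TOXIN_HIGHER:
        evidence.append(
            f"median A/T ratio {median:.2f} borderline; TIR consensus toxin_higher"
        )
        return assignment(3)
    if down_in_toxin:
        evidence.append(
            f"coverage step down at {changepoint.position} "
            f"(fold {changepoint.fold:.2f}) inside the toxin CDS"
        )
        return assignment(3)

    # (4) class 1, with the borderline band gated on TIR support
    if in_band:
        if verdict == ANTITOXIN_HIGHER:
            evidence.append(
                f"median A/T ratio {median:.2f} borderline; TIR consensus antitoxin_higher"
            )
            return assignment(1)
        evidence.append(
            f"median A/T ratio {median:.2f} borderline without TIR support"
        )
        return assignment("unclassified")
    evidence.append(f"median A/T ratio {median:.2f} below two-fold band; single transcript")
    return assignment(1)


def _proximal_second_external(operon: OperonModel, proximal_window: int):
    """The second external promoter whose TSS is near the first CDS start, if any.

    Promoters are ordered by TSS; only a non-first external promoter within
    ``proximal_window`` nt of the first CDS start qualifies (extra distal
    promoters do not create class-2 evidence).
    """
    external = sorted(operon.external_promoters(), key=lambda p: p.tss)
    first_cds = operon.genes[0].start
    for p in external[1:]:
        if abs(p.tss - first_cds) <= proximal_window:
            return p
    return None


def classification_report(assignments, ratios=None, consensuses=None, synthesis=None):
    """Tabular report: one row per operon (system, class, ratio band, consensus)."""
    import pandas as pd

    ratios = ratios or {}
    consensuses = consensuses or {}
    synthesis = synthesis or {}
    rows = []
    for a in assignments:
        r = ratios.get(a.operon_id)
        cons = _pick_consensus(consensuses.get(a.operon_id))
        syn = synthesis.get(a.operon_id)
        if syn is None:
            syn_col = "NA"
        elif syn.low_confidence:
            syn_col = "LC"
        else:
            syn_col = "+" if syn.ratio > 1 else "-"
        rows.append({
            "system": a.operon_id,
            "class": a.assigned_class,
            "mechanism": a.mechanism,
            "mrna_ratio": ("NA" if r is None or not r.included
                           else (">2" if r.median_ratio > 2 else "<2")),
            "consensus": cons.verdict if cons is not None else "NA",
            "synthesis": syn_col,
            "anomalies": ";".join(a.anomaly_flags) or "none",
        })
    return pd.DataFrame(rows)
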