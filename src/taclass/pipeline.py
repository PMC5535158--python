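"""End-to-end orchestration: file-based runs of the whole classification.

``run_pipeline`` drives the stages — annotation, coverage quantification,
replicate error, changepoint evidence, TIR consensus, classification —
over the file formats each module defines, and writes plain TSV reports
plus a machine-readable evidence JSON.  ``export_inputs`` serializes a
simulation (or the bundled fixture) into exactly those input formats, so a
simulated study round-trips through the same code paths as real data.
"""

from __future__ import annotations

import dataclasses
import glob
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from taclass import classifier, coverage_quant, profile_evidence, replicate_error
from taclass import operon_model, tir_consensus
from taclass.classifier import SynthesisRates
from taclass.synthetic_data import SimData

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """All paths and thresholds of one pipeline run.

    Round-trips through YAML unchanged (`save` / `load`).
    """

    gff3: str = ""
    fasta: str = ""
    operon_table: str = ""
    promoter_table: str = ""
    counts_glob: str = ""           # e.g. "counts/*.tsv"
    bedgraph: str = ""              # optional
    tir_table: str = ""             # optional
    synthesis_table: str = ""       # optional
    out_dir: str = "results"
    borderline_delta: float = 0.25
    proximal_window: int = 50
    min_segment: int = 50
    min_fold: float = 2.0
    bic_threshold: float = 10.0
    sd_ddof: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("borderline_delta", "proximal_window", "min_segment",
                     "min_fold", "bic_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def read_synthesis_table(path: str | os.PathLike) -> dict[str, SynthesisRates]:
    """TSV with columns operon_id, rate_antitoxin, rate_toxin,
    reads_antitoxin, reads_toxin [, relative_error]."""
    df = pd.read_csv(path, sep="\t", comment="#")
    out = {}
    for row in df.itertuples(index=False):
        out[str(row.operon_id)] = SynthesisRates(
            operon_id=str(row.operon_id),
            rate_antitoxin=float(row.rate_antitoxin),
            rate_toxin=float(row.rate_toxin),
            reads_antitoxin=int(row.reads_antitoxin),
            reads_toxin=int(row.reads_toxin),
            relative_error=float(getattr(row, "relative_error", 0.30)),
        )
    return out


def write_synthesis_table(path: str | os.PathLike,
                          synthesis: dict[str, SynthesisRates]) -> None:
    with open(path, "w") as fh:
        fh.write("operon_id\trate_antitoxin\trate_toxin\treads_antitoxin"
                 "\treads_toxin\trelative_error\n")
        for s in synthesis.values():
            fh.write(f"{s.operon_id}\t{s.rate_antitoxin:g}\t{s.rate_toxin:g}"
                     f"\t{s.reads_antitoxin}\t{s.reads_toxin}\t{s.relative_error:g}\n")


def export_inputs(data: SimData, out_dir: str | os.PathLike,
                  seqid: str = "synthetic") -> RunConfig:
    """Write a simulation's outputs in the pipeline's input formats.

    Produces GFF3 + FASTA + operon/promoter tables, one count TSV per
    dataset, a bedGraph of base profiles, TIR and synthesis TSVs, and a
    truths TSV; returns a RunConfig pointing at them.
    """
    out = Path(out_dir)
    (out / "counts").mkdir(parents=True, exist_ok=True)

    layout = operon_model.write_gff3(out / "annotation.gff3", data.operons, seqid=seqid)

    spacer = "A" * 200
    contig = "".join(
        (op.sequence or "N" * op.span) + spacer for op in data.operons
    )
    SeqIO.write([SeqRecord(Seq(contig), id=seqid, description="")],
                str(out / "annotation.fasta"), "fasta")

    with open(out / "operons.tsv", "w") as fh:
        fh.write("operon_id\tgene_id\trole\n")
        for op in data.operons:
            for g in op.genes:
                fh.write(f"{op.operon_id}\t{g.gene_id}\t{g.role}\n")
    with open(out / "promoters.tsv", "w") as fh:
        fh.write("operon_id\tpromoter_id\ttss\n")
        for op in data.operons:
            for p in op.promoters:
                fh.write(f"{op.operon_id}\t{p.promoter_id}\t{layout[op.operon_id] + p.tss}\n")

    for table in data.count_tables:
        coverage_quant.write_count_table(out / "counts" / f"{table.dataset_id}.tsv", table)

    profile_evidence.write_bedgraph(out / "profiles.bedgraph", data.profiles)
    tir_consensus.write_tir_table(out / "tir.tsv", data.tir_calls)
    write_synthesis_table(out / "synthesis.tsv", data.synthesis)

    with open(out / "truths.tsv", "w") as fh:
        fh.write("operon_id\ttrue_class\ttrue_ratio\tbreakpoint_pos\tinternal_promoter_pos\n")
        for t in data.truths.values():
            fh.write(f"{t.operon_id}\t{t.true_class}\t{t.true_ratio:g}"
                     f"\t{-1 if t.breakpoint_pos is None else t.breakpoint_pos}"
                     f"\t{-1 if t.internal_promoter_pos is None else t.internal_promoter_pos}\n")

    return RunConfig(
        gff3=str(out / "annotation.gff3"),
        fasta=str(out / "annotation.fasta"),
        operon_table=str(out / "operons.tsv"),
        promoter_table=str(out / "promoters.tsv"),
        counts_glob=str(out / "counts" / "*.tsv"),
        bedgraph=str(out / "profiles.bedgraph"),
        tir_table=str(out / "tir.tsv"),
        synthesis_table=str(out / "synthesis.tsv"),
        out_dir=str(out / "reports"),
    )


def _load_operons(config: RunConfig):
    try:
        roles = operon_model.read_operon_table(config.operon_table)
        promoters = (operon_model.read_promoter_table(config.promoter_table)
                     if config.promoter_table else None)
        sequences = None
        if config.fasta:
            sequences = {rec.id: str(rec.seq)
                         for rec in SeqIO.parse(config.fasta, "fasta")}
        return operon_model.read_annotation(config.gff3, roles, promoters, sequences)
    except (OSError, ValueError) as exc:
        raise StageError("operon_model", str(exc)) from exc


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage over the configured inputs and write all reports.

    Returns the in-memory evidence dictionary that is also written as
    ``evidence.json``.  Any stage failure raises :class:`StageError`
    naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    operons = _load_operons(config)
    log.info("operon_model: %d operons", len(operons))

    try:
        paths = sorted(glob.glob(config.counts_glob))
        if not paths:
            raise StageError("coverage_quant",
                             f"no count tables match {config.counts_glob!r}")
        tables = [coverage_quant.read_count_table(p) for p in paths]
    except (OSError, ValueError) as exc:
        raise StageError("coverage_quant", str(exc)) from exc

    summaries = {
        op.operon_id: coverage_quant.summarize_ratios(tables, op, ddof=config.sd_ddof)
        for op in operons
    }
    coverage_quant.ratio_report(list(summaries.values())).to_csv(
        out / "ratios.tsv", sep="\t", index=False)

    # replicate error: per condition, plus a pooled estimate per operon
    estimates = []
    for op in operons:
        per_condition = []
        by_cond: dict[str, list] = {}
        for t in tables:
            by_cond.setdefault(t.condition_id, []).append(t)
        for cond, cond_tables in sorted(by_cond.items()):
            reps = []
            for t in cond_tables:
                a, x = op.antitoxin, op.toxin
                ca = coverage_quant.rpkm(t.counts.get(a.gene_id, 0.0), a.length, t.total_mapped)
                ct = coverage_quant.rpkm(t.counts.get(x.gene_id, 0.0), x.length, t.total_mapped)
                reps.append((ca, ct))
            per_condition.append(replicate_error.log_error_decomposition(
                reps, operon_id=op.operon_id, condition_id=cond, ddof=config.sd_ddof))
        estimates.extend(per_condition)
        estimates.append(replicate_error.pooled_error(per_condition, operon_id=op.operon_id))
    replicate_error.error_report(estimates).to_csv(out / "errors.tsv", sep="\t", index=False)

    changepoints: dict[str, profile_evidence.ChangepointCall | None] = {}
    if config.bedgraph:
        try:
            profiles = profile_evidence.read_bedgraph(config.bedgraph)
        except (OSError, ValueError) as exc:
            raise StageError("profile_evidence", str(exc)) from exc
        for op in operons:
            call = None
            if op.operon_id in profiles:
                call = profile_evidence.detect_changepoint(
                    profiles[op.operon_id], min_segment=config.min_segment,
                    min_fold=config.min_fold, bic_threshold=config.bic_threshold)
                if call is not None:
                    profile_evidence.annotate_region(call, op)
            changepoints[op.operon_id] = call
        profile_evidence.changepoint_report(changepoints).to_csv(
            out / "changepoints.tsv", sep="\t", index=False)

    consensus_by_operon: dict[str, dict[str, tir_consensus.ConsensusCall]] = {}
    if config.tir_table:
        try:
            calls = tir_consensus.read_tir_table(config.tir_table)
        except (OSError, ValueError) as exc:
            raise StageError("tir_consensus", str(exc)) from exc
        for (operon_id, variant), cons in tir_consensus.consensus_by_variant(calls).items():
            consensus_by_operon.setdefault(operon_id, {})[variant] = cons
        pd.DataFrame(
            [{"operon_id": oid, "variant": v, "n_methods": c.n_methods,
              "verdict": c.verdict}
             for oid, by_v in consensus_by_operon.items()
             for v, c in sorted(by_v.items())]
        ).to_csv(out / "consensus.tsv", sep="\t", index=False)

    synthesis: dict[str, SynthesisRates] = {}
    if config.synthesis_table:
        try:
            synthesis = read_synthesis_table(config.synthesis_table)
        except (OSError, ValueError) as exc:
            raise StageError("classifier", str(exc)) from exc

    assignments = []
    for op in operons:
        assignments.append(classifier.classify(
            op, summaries[op.operon_id],
            changepoint=changepoints.get(op.operon_id),
            consensus_by_variant=consensus_by_operon.get(op.operon_id),
            synthesis=synthesis.get(op.operon_id),
            borderline_delta=config.borderline_delta,
            proximal_window=config.proximal_window,
        ))
    classifier.classification_report(
        assignments, ratios=summaries, consensuses=consensus_by_operon,
        synthesis=synthesis,
    ).to_csv(out / "classification.tsv", sep="\t", index=False)

    evidence = {
        a.operon_id: {
            "class": a.assigned_class,
            "mechanism": a.mechanism,
            "evidence": a.evidence,
            "anomaly_flags": a.anomaly_flags,
        }
        for a in assignments
    }
    with open(out / "evidence.json", "w") as fh:
        json.dump(evidence, fh, indent=2, sort_keys=True)
    log.info("classifier: %d assignments written to %s", len(assignments), out)
    return evidence
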