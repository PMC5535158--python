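"""RPKM coverage, antitoxin/toxin ratios, and the across-dataset summary.

Coverage is quantified as RPKM = 1e9 * n / (L * T), with n the fractional
read count of the CDS (multi-mapped reads contribute 0.5 each), L the CDS
length in nt, and T the dataset's total mapped reads.  The antitoxin/toxin
ratio is summarized by its median over datasets (13 in the reference study
design: one condition in triplicate plus five conditions in duplicate) and
its sample standard deviation, after an inclusion filter that drops operons
with under one read per base in more than half of the datasets.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from taclass.operon_model import OperonModel

log = logging.getLogger(__name__)


@dataclass
class CountTable:
    """Per-gene fractional read counts for one RNA-seq dataset."""

    dataset_id: str
    condition_id: str
    replicate_id: str
    counts: dict[str, float]
    total_mapped: float

    def __post_init__(self) -> None:
        for gene_id, n in self.counts.items():
            if n < 0:
                raise ValueError(f"{self.dataset_id}: negative count for {gene_id}")
            if round(2 * n) != 2 * n:
                raise ValueError(
                    f"{self.dataset_id}: count {n} for {gene_id} is not a "
                    "multiple of 0.5 (half-reads come from multi-mapping only)"
                )
        if self.counts and self.total_mapped < max(self.counts.values()):
            raise ValueError(f"{self.dataset_id}: total_mapped below a single gene count")


@dataclass
class RatioSummary:
    """Antitoxin/toxin coverage ratio of one operon across datasets."""

    operon_id: str
    per_dataset_ratio: dict[str, float] = field(default_factory=dict)
    median_ratio: float = float("nan")
    sd_ratio: float = float("nan")
    n_datasets: int = 0
    included: bool = False


def rpkm(n: float, L: float, T: float) -> float:
    """Reads per kilobase of CDS per million mapped reads: 1e9*n/(L*T)."""
    if L <= 0:
        raise ValueError(f"CDS length must be positive, got {L}")
    if T <= 0:
        raise ValueError(f"total mapped reads must be positive, got {T}")
    if n < 0:
        raise ValueError(f"read count must be non-negative, got {n}")
    return 1e9 * n / (L * T)


def at_ratio(table: CountTable, operon: OperonModel) -> float | None:
    """Antitoxin/toxin RPKM ratio for one dataset; None if undefined.

    The library size T cancels, so the ratio equals (n_A/L_A)/(n_T/L_T).
    A zero toxin count makes the ratio undefined; the dataset is excluded
    for this operon (no pseudocount is added).
    """
    a, t = operon.antitoxin, operon.toxin
    try:
        n_a, n_t = table.counts[a.gene_id], table.counts[t.gene_id]
    except KeyError as exc:
        raise KeyError(
            f"dataset {table.dataset_id}: no count for gene {exc.args[0]} "
            f"of operon {operon.operon_id}"
        ) from None
    if n_t == 0:
        log.warning(
            "dataset %s: zero toxin count for %s; ratio undefined, dataset excluded",
            table.dataset_id, operon.operon_id,
        )
        return None
    return rpkm(n_a, a.length, table.total_mapped) / rpkm(n_t, t.length, table.total_mapped)


def summarize_ratios(
    tables: list[CountTable],
    operon: OperonModel,
    ddof: int = 1,
    apply_filter: bool = True,
) -> RatioSummary:
    """Median and sample SD of the per-dataset A/T ratios for one operon.

    ``ddof=1`` selects the sample (m-1) standard deviation.  ``included``
    reflects :func:`coverage_filter` (and is False when no dataset yields a
    usable ratio).
    """
    ratios: dict[str, float] = {}
    for table in tables:
        r = at_ratio(table, operon)
        if r is not None:
            ratios[table.dataset_id] = r
    summary = RatioSummary(operon_id=operon.operon_id, per_dataset_ratio=ratios,
                           n_datasets=len(ratios))
    if not ratios:
        return summary
    values = np.asarray(list(ratios.values()), dtype=float)
    summary.median_ratio = float(np.median(values))
    summary.sd_ratio = float(np.std(values, ddof=ddof)) if len(values) > ddof else 0.0
    summary.included = coverage_filter(tables, operon) if apply_filter else True
    return summary


def coverage_filter(tables: list[CountTable], operon: OperonModel) -> bool:
    """Inclusion rule: drop an operon if either gene is under-covered.

    Returns False iff, for the toxin or the antitoxin, the per-base read
    density n/L falls below 1 in strictly more than half of the datasets.
    """
    n_tables = len(tables)
    for gene in (operon.toxin, operon.antitoxin):
        low = sum(
            1 for t in tables
            if t.counts.get(gene.gene_id, 0.0) / gene.length < 1.0
        )
        if low > n_tables / 2:
            return False
    return True


# ---------------------------------------------------------------------------
# TSV interfaces

def read_count_table(path: str | os.PathLike) -> CountTable:
    """Read one dataset's count TSV.

    Format: ``# key: value`` header lines for dataset_id, condition_id,
    replicate_id and total_mapped, then ``gene_id<TAB>count`` rows.
    """
    meta: dict[str, str] = {}
    with open(path) as fh:
        rows = []
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition(":")
                meta[key.strip()] = value.strip()
            elif line and not line.startswith("gene_id"):
                rows.append(line.split("\t"))
    for key in ("dataset_id", "condition_id", "replicate_id", "total_mapped"):
        if key not in meta:
            raise ValueError(f"count table {path}: missing header '# {key}: ...'")
    counts = {gene_id: float(value) for gene_id, value in rows}
    return CountTable(
        dataset_id=meta["dataset_id"],
        condition_id=meta["condition_id"],
        replicate_id=meta["replicate_id"],
        counts=counts,
        total_mapped=float(meta["total_mapped"]),
    )


def write_count_table(path: str | os.PathLike, table: CountTable) -> None:
    with open(path, "w") as fh:
        fh.write(f"# dataset_id: {table.dataset_id}\n")
        fh.write(f"# condition_id: {table.condition_id}\n")
        fh.write(f"# replicate_id: {table.replicate_id}\n")
        fh.write(f"# total_mapped: {table.total_mapped:g}\n")
        fh.write("gene_id\tcount\n")
        for gene_id, n in table.counts.items():
            fh.write(f"{gene_id}\t{n:g}\n")


def ratio_report(summaries: list[RatioSummary]) -> pd.DataFrame:
    """Tabular ratio report: one row per operon (system, A/T, St.Dev, n, included)."""
    return pd.DataFrame(
        [
            {
                "system": s.operon_id,
                "at_ratio": round(s.median_ratio, 2),
                "sd": round(s.sd_ratio, 2),
                "n_datasets": s.n_datasets,
                "included": s.included,
            }
            for s in summaries
        ]
    )
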