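"""Domain types and annotation I/O for two-gene toxin-antitoxin operons.

Coordinates are 0-based, half-open, and plus-strand-normalized per operon:
minus-strand operons are flipped on read so that transcription always runs
left to right in the internal frame.  This makes window arithmetic
(ribosome-binding-site windows, changepoint positions) unambiguous.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field

import gffutils
import pandas as pd

TOXIN = "toxin"
ANTITOXIN = "antitoxin"


@dataclass(frozen=True)
class GeneModel:
    """One CDS of a TA operon in the operon's internal frame.

    ``length`` is the CDS length in nucleotides (annotations need not
    include the stop codon, so divisibility by 3 is not required).
    """

    gene_id: str
    role: str  # "toxin" or "antitoxin"
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.role not in (TOXIN, ANTITOXIN):
            raise ValueError(f"unknown role {self.role!r} for gene {self.gene_id}")
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: end must exceed start")
        if self.length < 30:
            raise ValueError(f"gene {self.gene_id}: CDS shorter than 30 nt")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end


@dataclass(frozen=True)
class Promoter:
    """A transcription start site attached to an operon.

    Placement is derived, never stored: a promoter is *internal* iff its
    TSS lies strictly inside the span from the first CDS start to the last
    CDS end, and *external* otherwise.
    """

    promoter_id: str
    tss: int  # 0-based, operon frame

    def placement(self, operon: "OperonModel") -> str:
        first = operon.genes[0].start
        last = operon.genes[-1].end
        return "internal" if first < self.tss < last else "external"


@dataclass
class OperonModel:
    """A two-gene TA operon: exactly one toxin and one antitoxin CDS.

    ``genes`` are in transcription order.  ``sequence``, when present,
    covers the locus in transcription orientation; ``offset`` maps
    sequence position 0 to an operon-frame coordinate.
    """

    operon_id: str
    genes: list[GeneModel]
    promoters: list[Promoter] = field(default_factory=list)
    sequence: str | None = None
    offset: int = 0

    def __post_init__(self) -> None:
        roles = [g.role for g in self.genes]
        if roles.count(TOXIN) != 1 or roles.count(ANTITOXIN) != 1:
            raise ValueError(
                f"operon {self.operon_id}: needs exactly one toxin and one "
                f"antitoxin, got roles {roles}"
            )
        self.genes = sorted(self.genes, key=lambda g: g.start)
        a, b = self.genes
        if b.start < a.start and b.end > a.start:  # pragma: no cover - sorted above
            raise ValueError(f"operon {self.operon_id}: nested genes")
        if a.start < b.start < a.end and b.end <= a.end:
            raise ValueError(f"operon {self.operon_id}: nested genes")
        for p in self.promoters:
            if p.tss >= self.genes[-1].end:
                raise ValueError(
                    f"operon {self.operon_id}: promoter {p.promoter_id} TSS "
                    f"{p.tss} not upstream of last gene end {self.genes[-1].end}"
                )

    @property
    def span(self) -> int:
        return self.genes[-1].end

    @property
    def toxin(self) -> GeneModel:
        return next(g for g in self.genes if g.role == TOXIN)

    @property
    def antitoxin(self) -> GeneModel:
        return next(g for g in self.genes if g.role == ANTITOXIN)

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def external_promoters(self) -> list[Promoter]:
        return [p for p in self.promoters if p.placement(self) == "external"]

    def internal_promoters(self) -> list[Promoter]:
        return [p for p in self.promoters if p.placement(self) == "internal"]


def rbs_window(operon: OperonModel, gene: GeneModel, upstream: int = 20) -> tuple[int, int]:
    """Interval [start-upstream, start) upstream of a gene's start codon.

    Clipped at 0 in the operon frame.  The 20 nt default is a configurable
    working definition of the ribosome-binding-site extent; with
    ``upstream=0`` the interval is empty.
    """
    if gene not in operon.genes:
        raise ValueError(f"gene {gene.gene_id} does not belong to {operon.operon_id}")
    return (max(0, gene.start - upstream), gene.start)


def rbs_overlaps_upstream_gene(operon: OperonModel, upstream: int = 20) -> bool:
    """True iff the downstream gene's RBS window intersects the upstream CDS.

    Nine of the ten curated E. coli type II TA systems show this embedding;
    HicAB (non-overlapping genes, toxin first) is the exception.
    """
    first, second = operon.genes
    lo, hi = rbs_window(operon, second, upstream=upstream)
    return lo < first.end and hi > first.start


def read_operon_table(path: str | os.PathLike) -> dict[str, dict[str, str]]:
    """Read a TSV of (operon_id, gene_id, role) into {operon_id: {gene_id: role}}."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"operon_id", "gene_id", "role"}
    if not required.issubset(df.columns):
        raise ValueError(f"operon table {path}: needs columns {sorted(required)}")
    table: dict[str, dict[str, str]] = {}
    for row in df.itertuples(index=False):
        table.setdefault(row.operon_id, {})[row.gene_id] = row.role
    return table


def read_promoter_table(path: str | os.PathLike) -> dict[str, list[tuple[str, int]]]:
    """Read a TSV of (operon_id, promoter_id, tss) into {operon_id: [(id, tss)]}.

    TSS coordinates are genomic (same frame as the GFF3); they are mapped
    into the operon frame by :func:`read_annotation`.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    table: dict[str, list[tuple[str, int]]] = {}
    for row in df.itertuples(index=False):
        table.setdefault(str(row.operon_id), []).append((str(row.promoter_id), int(row.tss)))
    return table


def _revcomp(seq: str) -> str:
    comp = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")
    return seq.translate(comp)[::-1]


def read_annotation(
    gff3_path: str | os.PathLike,
    roles: dict[str, dict[str, str]],
    promoters: dict[str, list[tuple[str, int]]] | None = None,
    sequences: dict[str, str] | None = None,
) -> list[OperonModel]:
    """Build plus-strand-normalized OperonModels from GFF3 CDS features.

    Parameters
    ----------
    gff3_path:
        GFF3 with a CDS feature per gene; feature IDs (``ID=`` attribute)
        must match the gene_ids of ``roles``.
    roles:
        ``{operon_id: {gene_id: role}}`` — the curated operon membership
        table (operons are defined externally, not inferred from proximity).
    promoters:
        Optional ``{operon_id: [(promoter_id, genomic_tss)]}``.
    sequences:
        Optional ``{seqid: nucleotide string}`` from the companion FASTA.

    All genomic coordinates are re-expressed in an internal frame anchored
    at the operon's leftmost feature, and minus-strand operons are flipped
    (sequence reverse-complemented) so transcription runs left to right.
    """
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    cds_by_id: dict[str, gffutils.Feature] = {}
    for feat in db.features_of_type("CDS"):
        for fid in feat.attributes.get("ID", []):
            cds_by_id[fid] = feat

    operons: list[OperonModel] = []
    for operon_id, gene_roles in roles.items():
        feats = {}
        for gene_id in gene_roles:
            if gene_id not in cds_by_id:
                raise ValueError(
                    f"operon {operon_id}: no CDS feature for gene {gene_id} in {gff3_path}"
                )
            feats[gene_id] = cds_by_id[gene_id]
        strands = {f.strand for f in feats.values()}
        seqids = {f.seqid for f in feats.values()}
        if len(strands) != 1 or len(seqids) != 1:
            raise ValueError(f"operon {operon_id}: genes on mixed strands/contigs")
        strand = strands.pop()
        seqid = seqids.pop()

        # genomic 0-based half-open
        glo = min(f.start - 1 for f in feats.values())
        ghi = max(f.end for f in feats.values())
        prom_in = (promoters or {}).get(operon_id, [])
        # anchor the frame so upstream promoters get non-negative coordinates:
        # internal 0 sits at the transcription-upstream edge of the locus
        if strand == "+":
            anchor = min([glo] + [tss for _, tss in prom_in])
            to_frame_point = lambda g: g - anchor  # noqa: E731
            to_frame_iv = lambda s, e: (s - anchor, e - anchor)  # noqa: E731
        else:
            anchor = max([ghi - 1] + [tss for _, tss in prom_in])
            to_frame_point = lambda g: anchor - g  # noqa: E731
            to_frame_iv = lambda s, e: (anchor - e + 1, anchor - s + 1)  # noqa: E731

        genes = []
        for gene_id, f in feats.items():
            start, end = to_frame_iv(f.start - 1, f.end)
            genes.append(GeneModel(gene_id, gene_roles[gene_id], start, end))

        proms = [Promoter(pid, to_frame_point(tss)) for pid, tss in prom_in]

        seq = None
        if sequences and seqid in sequences:
            if strand == "+":
                seq = sequences[seqid][anchor:ghi]
            else:
                seq = _revcomp(sequences[seqid][glo:anchor + 1])

        operons.append(OperonModel(operon_id, genes, proms, sequence=seq))
    return operons


def write_gff3(path: str | os.PathLike, operons: list[OperonModel],
               seqid: str = "synthetic") -> dict[str, int]:
    """Write operon CDS features as a GFF3 file (plus strand, one contig frame).

    Operons are laid out end to end with a 200 nt spacer so that the file
    round-trips through :func:`read_annotation`.  Returns the genomic
    offset (cursor) of each operon's internal position 0, for writing
    companion promoter tables and FASTA in the same frame.
    """
    lines = ["##gff-version 3"]
    layout: dict[str, int] = {}
    cursor = 0
    for op in operons:
        layout[op.operon_id] = cursor
        for g in op.genes:
            lines.append(
                "\t".join([
                    seqid, "taclass", "CDS",
                    str(cursor + g.start + 1), str(cursor + g.end), ".", "+", "0",
                    f"ID={g.gene_id};operon={op.operon_id}",
                ])
            )
        cursor += op.span + 200
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return layout
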