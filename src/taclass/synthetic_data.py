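"""Fully labelled synthetic inputs for every pipeline stage.

``simulate`` emulates the reference study design: 13 replicate RNA-seq
count tables (one condition in triplicate + five conditions in duplicate),
negative-binomial per-gene counts, Poisson base-resolution coverage with
the transcript architecture of each class, and TIR sign tables with
class-consistent structure.  ``reference_fixture`` instead transcribes the
published ten-system evidence table (medians, promoter structure, TIR
signs, synthesis-rate flags) so the classifier can be checked against the
printed class labels without any sequencing data.

What the generator emulates — and what it does not — is documented in
docs/methods.md; in short, counts have realistic replicate noise but no
positional bias, batch structure, or sequence-dependent mappability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from taclass.classifier import SynthesisRates
from taclass.coverage_quant import CountTable, RatioSummary
from taclass.operon_model import ANTITOXIN, TOXIN, GeneModel, OperonModel, Promoter
from taclass.profile_evidence import BaseProfile
from taclass.tir_consensus import TirCall

DEFAULT_TRUE_RATIO = {1: 1.3, 2: 1.0, 3: 2.9, 4: 1.0}
DEFAULT_REPLICATE_DESIGN = [("cond1", 3)] + [(f"cond{i}", 2) for i in range(2, 7)]


@dataclass
class SimConfig:
    """Study-condition parameters for the generator.

    ``true_ratio_by_class`` is the full-operon antitoxin/toxin coverage
    ratio each class is built around; ``replicate_design`` lists
    (condition, replicate count) pairs — the default 1x3 + 5x2 gives the
    13 datasets of the reference design.  ``depth_mean`` is the expected
    toxin-gene coverage in reads/base; ``nb_dispersion`` the
    negative-binomial dispersion (variance = mu + dispersion*mu^2).
    """

    n_operons_per_class: int = 5
    true_ratio_by_class: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_RATIO))
    depth_mean: float = 50.0
    nb_dispersion: float = 0.1
    shared_noise_sd: float = 0.2  # ln-scale sd of the per-operon, per-dataset
    #                               expression factor both genes share (one
    #                               transcript => correlated replicate noise)
    toxin_length_range: tuple[int, int] = (250, 350)
    antitoxin_length_range: tuple[int, int] = (200, 300)
    replicate_design: list[tuple[str, int]] = field(
        default_factory=lambda: list(DEFAULT_REPLICATE_DESIGN))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_operons_per_class < 1:
            raise ValueError("need at least one operon per class")
        if self.nb_dispersion <= 0:
            raise ValueError("dispersion must be positive")


@dataclass
class SimTruth:
    operon_id: str
    true_class: int
    true_ratio: float
    breakpoint_pos: int | None = None
    internal_promoter_pos: int | None = None

    def __post_init__(self) -> None:
        if self.true_class == 3 and self.breakpoint_pos is None:
            raise ValueError("class 3 truth needs a breakpoint position")
        if self.true_class == 4 and self.internal_promoter_pos is None:
            raise ValueError("class 4 truth needs an internal promoter position")


@dataclass
class SimData:
    """Everything one simulation run produces."""

    operons: list[OperonModel]
    count_tables: list[CountTable]
    profiles: dict[str, BaseProfile]
    tir_calls: list[TirCall]
    synthesis: dict[str, SynthesisRates]
    truths: dict[str, SimTruth]


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> float:
    """Negative-binomial count with variance mean + dispersion*mean^2."""
    if mean <= 0:
        return 0.0
    size = 1.0 / dispersion
    p = size / (size + mean)
    return float(rng.negative_binomial(size, p))


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _make_operon(rng: np.random.Generator, operon_id: str, true_class: int,
                 config: SimConfig) -> tuple[OperonModel, SimTruth]:
    """Lay out one operon with the transcript architecture of its class.

    Classes 1 and 3 put the antitoxin upstream with the downstream RBS
    embedded in the upstream CDS (small gap); class 2 is HicA/HicB-like:
    toxin upstream, a >= 25 nt intergenic gap, and a second external
    promoter just upstream of the first CDS; class 4 is RnlA/RnlB-like:
    toxin upstream with an internal promoter inside the toxin CDS.
    """
    L_t = int(rng.integers(*config.toxin_length_range))
    L_a = int(rng.integers(*config.antitoxin_length_range))
    leader = 60

    if true_class in (1, 3):
        first_role, L1 = ANTITOXIN, L_a
        second_role, L2 = TOXIN, L_t
    else:
        first_role, L1 = TOXIN, L_t
        second_role, L2 = ANTITOXIN, L_a
    gap = int(rng.integers(25, 60)) if true_class == 2 else int(rng.integers(2, 12))

    g1 = GeneModel(f"{operon_id}_{first_role}", first_role, leader, leader + L1)
    g2 = GeneModel(f"{operon_id}_{second_role}", second_role,
                   g1.end + gap, g1.end + gap + L2)
    # the primary TSS anchors the operon frame at 0, so annotations written
    # to disk and re-read land in the identical internal frame
    promoters = [Promoter(f"{operon_id}_p1", 0)]
    breakpoint_pos = internal_promoter_pos = None
    if true_class == 2:
        # second external promoter within 30 nt of the first CDS start
        tss2 = g1.start - int(rng.integers(5, 31))
        promoters.append(Promoter(f"{operon_id}_p2", tss2))
    if true_class == 3:
        # truncation point inside the toxin CDS
        breakpoint_pos = int(g2.start + rng.integers(60, L2 - 60))
    if true_class == 4:
        # internal promoter inside the toxin CDS, upstream of the antitoxin;
        # NOT annotated: detection must come from the coverage step
        internal_promoter_pos = int(g1.start + rng.integers(60, L1 - 60))
    truth = SimTruth(operon_id, true_class,
                     config.true_ratio_by_class[true_class],
                     breakpoint_pos=breakpoint_pos,
                     internal_promoter_pos=internal_promoter_pos)

    seq = _random_sequence(rng, g2.end)
    operon = OperonModel(operon_id, [g1, g2], promoters, sequence=seq)
    return operon, truth


def _expected_coverage(operon: OperonModel, truth: SimTruth, depth: float) -> np.ndarray:
    """Expected reads/base along the operon implied by its transcript mix.

    Transcription starts at the most upstream external TSS, so the short
    head of the profile before it is (near) zero but the CDS leader is
    covered — as in real coverage tracks, where a step at the CDS boundary
    would be an artifact.
    """
    mu = np.zeros(operon.span)
    a = operon.antitoxin
    r = truth.true_ratio
    ext = operon.external_promoters()
    tss = min((p.tss for p in ext), default=0)
    mu[tss:] = depth  # transcribed region at baseline depth

    if truth.true_class in (1, 2):
        # single effective architecture: antitoxin region scaled by the
        # true ratio (class 2's two external TSS are a few nt apart and
        # unresolvable, so they contribute one aggregate level)
        mu[a.start:a.end] = depth * r
    elif truth.true_class == 3:
        # full + truncated transcript: high before the breakpoint, low after
        b = truth.breakpoint_pos
        mu[tss:b] = depth * r
        mu[b:] = depth
    elif truth.true_class == 4:
        # full transcript at depth; the antitoxin-only transcript from the
        # internal promoter adds coverage downstream of it
        p = truth.internal_promoter_pos
        mu[p:] = depth * 3.0
    return mu


def _gene_mean_counts(operon: OperonModel, truth: SimTruth, depth: float) -> dict[str, float]:
    """Expected fractional read counts per gene (coverage integrated over the CDS)."""
    mu = _expected_coverage(operon, truth, depth)
    out = {}
    for g in operon.genes:
        if truth.true_class == 4:
            # whole-operon read counting sees both transcripts equally for
            # the region each covers; keep the *counted* ratio at true_ratio
            # (full-operon quantification, matching a near-1 printed ratio)
            out[g.gene_id] = depth * g.length * (
                truth.true_ratio if g.role == ANTITOXIN else 1.0)
        else:
            out[g.gene_id] = float(mu[g.start:g.end].sum())
    return out


_CLASS_SIGNS = {
    # (rbs_calculator, utr_designer, barrick): True = antitoxin higher
    1: (True, True, True),
    2: (True, False, True),   # majority antitoxin_higher (post-variant-P2 picture)
    3: (False, False, True),  # majority toxin_higher
    4: (True, True, False),   # mixed, majority antitoxin_higher
}


def _tir_calls_for(rng: np.random.Generator, operon_id: str, true_class: int) -> list[TirCall]:
    calls = []
    for method, a_higher in zip(("rbs_calculator", "utr_designer", "barrick"),
                                _CLASS_SIGNS[true_class]):
        hi = float(rng.uniform(500, 5000))
        lo = hi / float(rng.uniform(2, 20))
        ta, tt = (hi, lo) if a_higher else (lo, hi)
        calls.append(TirCall(operon_id, method, "P1", ta, tt))
    return calls


def simulate(config: SimConfig) -> SimData:
    """Generate labelled operons, count tables, profiles, TIR and synthesis data.

    All draws come from one seeded generator, so a fixed ``config.seed``
    gives byte-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    operons, truths = [], {}
    for true_class in (1, 2, 3, 4):
        for i in range(config.n_operons_per_class):
            operon_id = f"sim_c{true_class}_{i:03d}"
            op, truth = _make_operon(rng, operon_id, true_class, config)
            operons.append(op)
            truths[operon_id] = truth

    # replicate count tables
    count_tables = []
    k = 0
    for condition, n_reps in config.replicate_design:
        for rep in range(1, n_reps + 1):
            k += 1
            counts = {}
            for op in operons:
                means = _gene_mean_counts(op, truths[op.operon_id], config.depth_mean)
                # both genes ride the same transcript, so replicate-to-replicate
                # expression fluctuations hit them together: shared lognormal
                # factor on top of independent counting noise
                factor = float(rng.lognormal(0.0, config.shared_noise_sd))
                for gene_id, mu in means.items():
                    counts[gene_id] = _nb_draw(rng, mu * factor, config.nb_dispersion)
            total = max(1.0, sum(counts.values())) * 50.0  # operons ~2% of library
            count_tables.append(CountTable(
                dataset_id=f"ds{k:02d}", condition_id=condition,
                replicate_id=f"rep{rep}", counts=counts, total_mapped=round(total)))

    # base profiles (Poisson noise around the architecture's expectation)
    profiles = {}
    for op in operons:
        mu = _expected_coverage(op, truths[op.operon_id], config.depth_mean)
        profiles[op.operon_id] = BaseProfile(op.operon_id, rng.poisson(mu).astype(float))

    # TIR sign tables and synthesis rates with class-consistent structure
    tir_calls = []
    synthesis = {}
    for op in operons:
        truth = truths[op.operon_id]
        tir_calls.extend(_tir_calls_for(rng, op.operon_id, truth.true_class))
        a_rate = float(rng.uniform(1.0, 10.0))
        t_rate = a_rate / 3.0 if truth.true_class != 4 else a_rate * 2.0
        reads = int(rng.integers(200, 5000))
        synthesis[op.operon_id] = SynthesisRates(
            op.operon_id, a_rate, t_rate, reads_antitoxin=reads, reads_toxin=reads)

    return SimData(operons, count_tables, profiles, tir_calls, synthesis, truths)


# ---------------------------------------------------------------------------
# The published ten-system evidence table, transcribed as a fixture

# system -> (median A/T, SD, class, promoter layout, signs by variant,
#            synthesis column: '+', '-', or 'LC')
_SYSTEMS: dict[str, dict] = {
    "FicAT":      dict(median=1.99, sd=0.53, cls=1, layout="1ex",
                       signs={"P1": (True, True, True)}, synthesis="+", lc=True),
    "YefM-YoeB":  dict(median=1.89, sd=0.42, cls=1, layout="1ex",
                       signs={"P1": (True, True, True)}, synthesis="+", lc=False),
    "MazEF":      dict(median=1.42, sd=0.25, cls=1, layout="1ex",
                       signs={"P1": (True, True, True)}, synthesis="+", lc=False),
    "PrlF-YhaV":  dict(median=1.11, sd=0.27, cls=1, layout="1ex",
                       signs={"P1": (True, True, True)}, synthesis="+", lc=False),
    "MqsAR":      dict(median=0.69, sd=0.16, cls=1, layout="1ex",
                       signs={"P1": (False, True, True)}, synthesis="+", lc=False),
    "RelBE":      dict(median=0.95, sd=0.10, cls=1, layout="1ex",
                       signs={"P1": (True, True, True)}, synthesis="+", lc=False),
    "HicAB":      dict(median=0.93, sd=0.20, cls=2, layout="2ex",
                       signs={"P1": (False, False, True),
                              "P2": (True, False, True)}, synthesis="+", lc=True),
    "DinJ-YafQ":  dict(median=2.89, sd=0.35, cls=3, layout="1ex",
                       signs={"P1": (True, False, False)}, synthesis="+", lc=False),
    "YafNO":      dict(median=2.08, sd=0.39, cls=3, layout="1ex",
                       signs={"P1": (True, False, False)}, synthesis="+", lc=False),
    "RnlAB":      dict(median=1.01, sd=0.25, cls=4, layout="1ex+1in",
                       signs={"P1": (True, True, False)}, synthesis="-", lc=False),
}

# FicAT and HicAB have under-128-read ribosome-profiling coverage (low
# confidence); the sign shown for them is never used by the classifier.


@dataclass
class ReferenceFixture:
    operons: list[OperonModel]
    ratios: dict[str, RatioSummary]
    tir_calls: list[TirCall]
    synthesis: dict[str, SynthesisRates]
    expected_class: dict[str, int]


def reference_fixture() -> ReferenceFixture:
    """The ten curated E. coli systems with their published evidence.

    Operon geometry is schematic (coordinates are synthetic stand-ins that
    realize the documented promoter layout and gene order); medians, SDs,
    TIR signs and synthesis flags are the published values, so running
    :func:`taclass.classifier.classify` over this fixture must reproduce
    the published class of every system.
    """
    operons, ratios, tir_calls, synthesis, expected = [], {}, [], {}, {}
    for name, row in _SYSTEMS.items():
        # schematic geometry: classes 2 and 4 are toxin-first, rest antitoxin-first
        toxin_first = row["cls"] in (2, 4)
        gap = 40 if row["cls"] == 2 else 5
        first_role = TOXIN if toxin_first else ANTITOXIN
        second_role = ANTITOXIN if toxin_first else TOXIN
        g1 = GeneModel(f"{name}_{first_role}", first_role, 60, 60 + 300)
        g2 = GeneModel(f"{name}_{second_role}", second_role,
                       g1.end + gap, g1.end + gap + 250)
        promoters = [Promoter(f"{name}_p1", 5)]
        if row["layout"] == "2ex":
            promoters.append(Promoter(f"{name}_p2", g1.start - 20))
        if row["layout"] == "1ex+1in":
            # internal promoter inside the upstream toxin CDS, upstream of
            # the antitoxin (RnlA/RnlB-like architecture)
            promoters.append(Promoter(f"{name}_pin", g1.start + 150))
        operons.append(OperonModel(name, [g1, g2], promoters))

        ratios[name] = RatioSummary(
            operon_id=name, per_dataset_ratio={}, median_ratio=row["median"],
            sd_ratio=row["sd"], n_datasets=13, included=True)

        for variant, signs in row["signs"].items():
            for method, a_higher in zip(("rbs_calculator", "utr_designer", "barrick"),
                                        signs):
                ta, tt = (2.0, 1.0) if a_higher else (1.0, 2.0)
                tir_calls.append(TirCall(name, method, variant, ta, tt))

        a_rate, t_rate = (2.0, 1.0) if row["synthesis"] == "+" else (1.0, 2.0)
        reads = 64 if row["lc"] else 1000
        synthesis[name] = SynthesisRates(name, a_rate, t_rate,
                                         reads_antitoxin=reads, reads_toxin=reads)
        expected[name] = row["cls"]

    return ReferenceFixture(operons, ratios, tir_calls, synthesis, expected)
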