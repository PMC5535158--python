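"""Translation-initiation-rate (TIR) layer: sign calls and 2-of-3 consensus.

TIR calculators (thermodynamic RBS models, empirical regressions) disagree
wildly on absolute rates, so predictions enter the classification only at
sign level: for each operon and transcript variant, does a method predict
the antitoxin TIR above or below the toxin TIR?  A consensus requires a
majority among the available methods; with fewer than two usable calls the
verdict is "insufficient".

External calculators are run outside this package and their outputs read
from TSV.  A built-in window scorer is provided as a clearly labelled
surrogate: a log-linear score over the -11..0 window upstream of the start
codon with a Shine-Dalgarno complementarity term — useful for exercising
the pipeline, never a reimplementation of the external tools.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass
from importlib import resources

import pandas as pd
import yaml

log = logging.getLogger(__name__)

ANTITOXIN_HIGHER = "antitoxin_higher"
TOXIN_HIGHER = "toxin_higher"
INSUFFICIENT = "insufficient"

METHODS = ("rbs_calculator", "utr_designer", "barrick", "builtin")

SD_CONSENSUS = "AGGAGG"


@dataclass(frozen=True)
class TirCall:
    """One method's antitoxin vs toxin TIR prediction for one transcript variant."""

    operon_id: str
    method: str
    transcript_variant: str
    tir_antitoxin: float
    tir_toxin: float

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown TIR method {self.method!r}")
        if self.tir_antitoxin == self.tir_toxin:
            raise ValueError(
                f"{self.operon_id}/{self.method}: tied TIR values carry no sign"
            )

    @property
    def sign(self) -> str:
        return ANTITOXIN_HIGHER if self.tir_antitoxin > self.tir_toxin else TOXIN_HIGHER


@dataclass(frozen=True)
class ConsensusCall:
    operon_id: str
    transcript_variant: str
    n_methods: int
    verdict: str


def consensus(calls: list[TirCall]) -> ConsensusCall:
    """Majority sign over the available method calls (2-of-3 rule).

    All calls must refer to one operon and transcript variant.  Fewer than
    two calls, or an exact split, yields "insufficient".
    """
    if not calls:
        return ConsensusCall("", "", 0, INSUFFICIENT)
    ids = {(c.operon_id, c.transcript_variant) for c in calls}
    if len(ids) > 1:
        raise ValueError(f"consensus over mixed operons/variants: {sorted(ids)}")
    operon_id, variant = ids.pop()
    n = len(calls)
    if n < 2:
        return ConsensusCall(operon_id, variant, n, INSUFFICIENT)
    up = sum(1 for c in calls if c.sign == ANTITOXIN_HIGHER)
    down = n - up
    if up == down:
        return ConsensusCall(operon_id, variant, n, INSUFFICIENT)
    verdict = ANTITOXIN_HIGHER if up > down else TOXIN_HIGHER
    return ConsensusCall(operon_id, variant, n, verdict)


def consensus_by_variant(calls: list[TirCall]) -> dict[tuple[str, str], ConsensusCall]:
    """Group calls by (operon_id, variant) and take the consensus of each group."""
    groups: dict[tuple[str, str], list[TirCall]] = {}
    for c in calls:
        groups.setdefault((c.operon_id, c.transcript_variant), []).append(c)
    return {key: consensus(group) for key, group in groups.items()}


def read_tir_table(path: str | os.PathLike) -> list[TirCall]:
    """Read TIR calls from a TSV with columns
    operon_id, method, variant, tir_antitoxin, tir_toxin.

    Rows with non-numeric or tied TIR values are rejected with a warning.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"operon_id", "method", "variant", "tir_antitoxin", "tir_toxin"}
    if not required.issubset(df.columns):
        raise ValueError(f"TIR table {path}: needs columns {sorted(required)}")
    calls = []
    for row in df.itertuples(index=False):
        try:
            ta, tt = float(row.tir_antitoxin), float(row.tir_toxin)
            if not (math.isfinite(ta) and math.isfinite(tt)):
                raise ValueError
        except (TypeError, ValueError):
            log.warning("TIR table %s: non-numeric row for %s/%s rejected",
                        path, row.operon_id, row.method)
            continue
        try:
            calls.append(TirCall(str(row.operon_id), str(row.method),
                                 str(row.variant), ta, tt))
        except ValueError as exc:
            log.warning("TIR table %s: row rejected (%s)", path, exc)
    return calls


def write_tir_table(path: str | os.PathLike, calls: list[TirCall]) -> None:
    with open(path, "w") as fh:
        fh.write("operon_id\tmethod\tvariant\ttir_antitoxin\ttir_toxin\n")
        for c in calls:
            fh.write(f"{c.operon_id}\t{c.method}\t{c.transcript_variant}"
                     f"\t{c.tir_antitoxin!r}\t{c.tir_toxin!r}\n")


# ---------------------------------------------------------------------------
# Built-in surrogate window scorer


def load_scorer_config(path: str | os.PathLike | None = None) -> dict:
    """Load scorer coefficients; the bundled surrogate config by default."""
    if path is None:
        text = resources.files("taclass.data").joinpath("barrick_surrogate.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    config = yaml.safe_load(text)
    for key in ("asd_weight", "optimal_spacing", "spacing_penalty", "base_weights"):
        if key not in config:
            raise ValueError(f"scorer config missing key {key!r}")
    return config


def builtin_window_score(
    sequence: str,
    start_codon_pos: int,
    config: dict | None = None,
    window: tuple[int, int] = (-11, 0),
) -> float:
    """Log-linear surrogate TIR score for the window upstream of a start codon.

    The score sums a per-position base weight over window offsets
    ``window[0]..window[1]`` (inclusive, relative to the first base of the
    start codon) plus the best Shine-Dalgarno term over all placements of
    a hexamer inside the window: ``asd_weight`` per base matching the SD
    consensus AGGAGG minus ``spacing_penalty`` per nt that the hexamer's
    spacing to the start codon deviates from ``optimal_spacing``.

    Arbitrary units; only comparisons between scores are meaningful.
    """
    if config is None:
        config = load_scorer_config()
    lo = start_codon_pos + window[0]
    hi = start_codon_pos + window[1] + 1
    if lo < 0 or hi > len(sequence):
        raise ValueError(
            f"window [{window[0]}, {window[1]}] around position {start_codon_pos} "
            f"falls off the sequence (length {len(sequence)})"
        )
    win = sequence[lo:hi].upper()

    base_w = config["base_weights"]
    pos_w = config.get("position_weights") or {}
    score = 0.0
    for i, base in enumerate(win):
        offset = window[0] + i
        weights = pos_w.get(offset, base_w)
        score += float(weights.get(base, 0.0))

    k = len(SD_CONSENSUS)
    best_sd = 0.0
    for i in range(0, len(win) - k + 1):
        matches = sum(1 for a, b in zip(win[i:i + k], SD_CONSENSUS) if a == b)
        # spacing: nt between hexamer 3' end and the start codon first base
        spacing = -(window[0] + i + k)
        term = (matches * float(config["asd_weight"])
                - abs(spacing - int(config["optimal_spacing"])) * float(config["spacing_penalty"]))
        best_sd = max(best_sd, term)
    return score + best_sd


def builtin_calls(
    operon,
    config: dict | None = None,
    variant: str = "P1",
) -> TirCall | None:
    """Score both genes of an operon with the surrogate scorer.

    Requires the operon to carry its locus sequence.  Returns None on a
    tie (no sign) or if either window falls off the sequence.
    """
    if operon.sequence is None:
        raise ValueError(f"operon {operon.operon_id} has no sequence")
    try:
        seq = operon.sequence
        off = operon.offset
        ta = builtin_window_score(seq, operon.antitoxin.start - off, config)
        tt = builtin_window_score(seq, operon.toxin.start - off, config)
    except ValueError:
        return None
    if ta == tt:
        return None
    return TirCall(operon.operon_id, "builtin", variant, ta, tt)
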