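"""Replicate log-error decomposition along the ratio and magnitude axes.

For replicate coverages (cA, cT) of the antitoxin and toxin, the error of
the log-ratio is the standard error of ln(cA) - ln(cT) = ln(cA/cT) across
replicates, and the error of the log-magnitude is the standard error of
ln(cA) + ln(cT) = ln(cA*cT).  The two directions are orthogonal axes of a
log-log coverage scatter: a rotated error bar along the ratio direction
shows how reproducible the A/T ratio itself is, independent of overall
expression level.  The log-ratio error is exactly zero whenever the ratio
is constant across replicates, however variable the magnitude.

Both errors are also reported in log10 units (divided by ln 10) for
plotting in base-10 log space.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)


@dataclass
class ErrorEstimate:
    """Standard errors of ln(cA/cT) and ln(cA*cT) over replicates."""

    operon_id: str
    condition_id: str
    n_replicates: int
    se_log_ratio: float
    se_log_magnitude: float
    defined: bool = True

    @property
    def se_log10_ratio(self) -> float:
        return self.se_log_ratio / math.log(10)

    @property
    def se_log10_magnitude(self) -> float:
        return self.se_log_magnitude / math.log(10)


def log_error_decomposition(
    replicate_coverages: list[tuple[float, float]],
    operon_id: str = "",
    condition_id: str = "",
    ddof: int = 1,
) -> ErrorEstimate:
    """Standard errors of the log-ratio and log-magnitude over replicates.

    Replicates with a zero coverage are dropped (with a warning) since
    their logs are undefined; with fewer than two usable replicates the
    estimate is flagged undefined (``defined=False``, SEs NaN).
    """
    usable = []
    for ca, ct in replicate_coverages:
        if ca <= 0 or ct <= 0:
            log.warning(
                "%s/%s: replicate with non-positive coverage (%g, %g) dropped",
                operon_id, condition_id, ca, ct,
            )
            continue
        usable.append((ca, ct))
    m = len(usable)
    if m < 2:
        return ErrorEstimate(operon_id, condition_id, m, float("nan"), float("nan"),
                             defined=False)
    la = np.log([ca for ca, _ in usable])
    lt = np.log([ct for _, ct in usable])
    se_ratio = float(np.std(la - lt, ddof=ddof) / math.sqrt(m))
    se_mag = float(np.std(la + lt, ddof=ddof) / math.sqrt(m))
    return ErrorEstimate(operon_id, condition_id, m, se_ratio, se_mag)


def pooled_error(estimates: list[ErrorEstimate], operon_id: str = "",
                 label: str = "pooled") -> ErrorEstimate:
    """Pool per-condition estimates by averaging their variances.

    The pooled SE is sqrt(mean(se^2)) over the defined per-condition
    estimates — each condition contributes equally, mirroring a design
    where conditions have similar replicate counts.
    """
    defined = [e for e in estimates if e.defined]
    if not defined:
        return ErrorEstimate(operon_id, label, 0, float("nan"), float("nan"),
                             defined=False)
    se_r = math.sqrt(float(np.mean([e.se_log_ratio ** 2 for e in defined])))
    se_m = math.sqrt(float(np.mean([e.se_log_magnitude ** 2 for e in defined])))
    n = sum(e.n_replicates for e in defined)
    return ErrorEstimate(operon_id, label, n, se_r, se_m)


def error_report(estimates: list[ErrorEstimate]):
    """TSV-ready table of per-condition (and pooled) error estimates."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "operon_id": e.operon_id,
                "condition_id": e.condition_id,
                "n": e.n_replicates,
                "se_log10_ratio": e.se_log10_ratio,
                "se_log10_magnitude": e.se_log10_magnitude,
                "defined": e.defined,
            }
            for e in estimates
        ]
    )
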