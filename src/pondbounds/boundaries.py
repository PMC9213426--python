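"""Cross-metric aggregation of boundary estimates per gradient.

Each gradient (surface area, depth, emergent vegetation cover) yields one
boundary estimate per ecosystem metric whose optimal fit was nonlinear.  These
are summarised — unweighted arithmetic mean, SE of the mean (sample SD/sqrt n)
and median, on the original back-transformed scale — and a one-sample t-test
compares a gradient's estimates against an external reference threshold (e.g.
the 30% emergent-vegetation wetland bound).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model_selection import BoundaryEstimate

__all__ = ["BoundaryEstimate", "BoundarySummary", "summarize_boundaries", "one_sample_t"]


class UndefinedTError(ValueError):
    """The t statistic is undefined (zero sample variance)."""


@dataclass
class BoundarySummary:
    """Per-gradient summary across metrics: mean +/- SE and median."""

    gradient: str
    n_estimates: int
    mean: float
    se_of_mean: float
    median: float


def summarize_boundaries(estimates: list[BoundaryEstimate] | np.ndarray) -> BoundarySummary:
    """Aggregate point estimates for one gradient.

    Accepts either ``BoundaryEstimate`` objects (all sharing one gradient) or a
    plain array of point estimates in original units.  Values are never rounded
    here; rounding belongs to presentation.
    """
    if len(estimates) == 0:
        raise ValueError("no boundary estimates to summarize")
    if isinstance(estimates[0], BoundaryEstimate):
        gradients = {e.gradient for e in estimates}
        if len(gradients) != 1:
            raise ValueError(f"estimates span multiple gradients: {sorted(gradients)}")
        gradient = next(iter(gradients))
        values = np.array([e.estimate for e in estimates], dtype=float)
    else:
        gradient = "x"
        values = np.asarray(estimates, dtype=float)
    n = len(values)
    se = float(np.std(values, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return BoundarySummary(
        gradient=gradient,
        n_estimates=n,
        mean=float(np.mean(values)),
        se_of_mean=se,
        median=float(np.median(values)),
    )


def one_sample_t(values, mu0: float) -> tuple[float, int, float]:
    """Two-sided one-sample t-test of mean(values) against mu0.

    Returns ``(t, df, p)`` with t = (mean - mu0)/(SD/sqrt(n)) and df = n - 1.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("one-sample t-test needs n >= 2")
    if not np.isfinite(values).all():
        raise ValueError("values must be finite")
    sd = np.std(values, ddof=1)
    if sd == 0:
        raise UndefinedTError("zero sample variance; t undefined")
    t = float((np.mean(values) - mu0) / (sd / np.sqrt(n)))
    df = n - 1
    p = float(2.0 * stats.t.sf(abs(t), df))
    return t, df, p
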