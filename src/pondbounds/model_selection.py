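"""AICc-based choice among the four candidate forms, with parsimony override.

The provisional winner is the converged fit with the minimum AICc.  A strictly
simpler form (smaller k) displaces it when it lies within ``threshold`` AICc
units of the minimum (default 11) *and* its RMSE exceeds the winner's by at
most ``rmse_rel_tol`` relative (default 10%) — one concrete instantiation of
"minimum AICc with consideration of fits within 11 units using RMSE and
parsimony".  The full AICc table is always retained so users can apply their
own judgment.

When the selected form is segmented or logistic, the breakpoint/inflection
parameter is the estimated functional boundary; it is back-transformed to
original gradient units (10**bp for log10-scaled gradients, where the SE
becomes a multiplicative factor 10**SE).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import models
from .models import FORMS, LOG10, ModelFit

logger = logging.getLogger("pondbounds")

_FORM_ORDER = {form: i for i, form in enumerate(FORMS)}  # null < linear < segmented < logistic


class SelectionImpossibleError(ValueError):
    """No converged fit was available to select among."""


@dataclass
class BoundaryEstimate:
    """A breakpoint/inflection back-transformed to original gradient units.

    ``se`` is a multiplicative factor (10**SE_log10) for log10-scaled gradients
    and additive (same units as the estimate) otherwise; ``se_kind`` records
    which.
    """

    gradient: str
    metric: str
    estimate: float
    se: float | None
    source: str  # "breakpoint" (segmented) | "inflection" (logistic)
    se_kind: str = "multiplicative"


@dataclass
class ModelComparison:
    """The four fits, their AICc gaps, and the selected form."""

    fits: dict[str, ModelFit]
    delta_aicc: dict[str, float]
    selected: str
    candidate_set: list[str]
    threshold: float
    selection_rule_applied: str = "min_aicc"

    @property
    def selected_fit(self) -> ModelFit:
        return self.fits[self.selected]


def compare_models(
    fits: dict[str, ModelFit],
    threshold: float = 11.0,
    rmse_rel_tol: float = 0.10,
) -> ModelComparison:
    """Select the optimal form from a set of fits.

    Non-converged fits are excluded (and logged) before selection.  AICc ties
    break toward smaller k, then the fixed complexity order
    null < linear < segmented < logistic.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    usable = {form: fit for form, fit in fits.items() if fit.converged}
    excluded = sorted(set(fits) - set(usable))
    if excluded:
        logger.info("selection: excluded non-converged fit(s): %s", ", ".join(excluded))
    if not usable:
        raise SelectionImpossibleError("no converged fits to select among")

    def sort_key(form: str):
        fit = usable[form]
        return (fit.aicc, fit.k, _FORM_ORDER[form])

    winner = min(usable, key=sort_key)
    min_aicc = usable[winner].aicc
    delta = {form: fit.aicc - min_aicc for form, fit in usable.items()}
    candidates = sorted(
        (form for form in usable if delta[form] <= threshold),
        key=lambda form: (usable[form].k, _FORM_ORDER[form]),
    )

    selected, rule = winner, "min_aicc"
    winner_rmse = usable[winner].rmse
    for form in candidates:  # simplest-first
        if form == winner:
            break
        if usable[form].k >= usable[winner].k:
            continue
        if winner_rmse == 0.0:
            break  # nothing simpler can match a perfect fit
        if usable[form].rmse <= winner_rmse * (1.0 + rmse_rel_tol):
            selected, rule = form, "parsimony_override"
            break

    return ModelComparison(
        fits=usable,
        delta_aicc=delta,
        selected=selected,
        candidate_set=candidates,
        threshold=threshold,
        selection_rule_applied=rule,
    )


def back_transform(value: float, x_transform: str) -> float:
    return 10.0 ** value if x_transform == LOG10 else value


def extract_boundary(
    comparison: ModelComparison,
    x_transform: str,
    gradient: str = "x",
    metric: str = "y",
) -> BoundaryEstimate | None:
    """Boundary from the selected fit, or None for null/linear winners."""
    fit = comparison.selected_fit
    if fit.form not in (models.SEGMENTED, models.LOGISTIC):
        return None
    source = "breakpoint" if fit.form == models.SEGMENTED else "inflection"
    bp = fit.params["bp"]
    if x_transform == LOG10:
        estimate = 10.0 ** bp
        se = 10.0 ** fit.bp_se if fit.bp_se is not None else None
        se_kind = "multiplicative"
    else:
        estimate = bp
        se = fit.bp_se
        se_kind = "additive"
    return BoundaryEstimate(
        gradient=gradient,
        metric=metric,
        estimate=float(estimate),
        se=None if se is None else float(se),
        source=source,
        se_kind=se_kind,
    )
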