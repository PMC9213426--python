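"""Synthetic gradient datasets and waterbody populations.

Two generators make every downstream stage testable without external data:

* ``generate_gradient`` inverts the four candidate forms into data-generating
  processes — x uniform on the (possibly log10) gradient scale, y = form(x)
  plus Gaussian noise on the transformed response scale, the scale on which
  the Gaussian likelihood is later computed.  True parameters travel with the
  dataset for recovery tests.
* ``generate_population`` draws waterbody records by type (pond / lake /
  wetland) with log-normal nutrient and chlorophyll distributions, normal pH,
  type-specific morphometry ranges, and Bernoulli hydroperiod/origin mixtures
  defaulting to 74% permanent and 65% constructed, the mixture observed in the
  compiled pond literature.

Per-type metric distribution parameters are qualitative placeholders (the
orderings are reported in the source literature only graphically); they are
configurable and must not be read as empirical estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classification import WaterbodyRecord
from .models import FORMS, IDENTITY, LOG10, GradientDataset, predict

#: Default gradient domains in original units (area ha, depth m, vegetation %).
DEFAULT_X_DOMAINS = {
    "surface_area": (1e-3, 1e3),
    "max_depth": (0.1, 50.0),
    "emergent_veg": (0.0, 100.0),
}

_REQUIRED_PARAMS = {
    "null": {"a"},
    "linear": {"b", "c"},
    "segmented": {"d1", "d2", "e1", "bp"},   # e2 optional (continuous if absent)
    "logistic": {"f", "g", "bp", "h"},
}


class SpecValidationError(ValueError):
    """A generator spec field violates its invariants."""

    def __init__(self, spec_field: str, message: str) -> None:
        self.spec_field = spec_field
        super().__init__(f"{spec_field}: {message}")


@dataclass
class GeneratorSpec:
    """Recipe for one synthetic gradient dataset.

    ``x_domain`` is given in original units and sampled uniformly on
    ``x_scale`` ("log10" or "identity"); for segmented/logistic forms the
    location parameter ``bp`` (on the transformed scale) must lie strictly
    inside the transformed domain.
    """

    form: str
    params: dict[str, float]
    x_domain: tuple[float, float] = (1e-3, 1e3)
    x_scale: str = LOG10
    n: int = 100
    noise_sd: float = 0.3
    seed: int = 0
    x_name: str = "x"
    y_name: str = "y"
    y_transform: str = IDENTITY  # recorded on the output dataset only

    def validate(self) -> None:
        if self.form not in FORMS:
            raise SpecValidationError("form", f"must be one of {FORMS}, got {self.form!r}")
        missing = _REQUIRED_PARAMS[self.form] - set(self.params)
        if missing:
            raise SpecValidationError("params", f"missing {sorted(missing)} for form {self.form!r}")
        if self.n < 2:
            raise SpecValidationError("n", f"must be >= 2, got {self.n}")
        if self.noise_sd < 0:
            raise SpecValidationError("noise_sd", f"must be >= 0, got {self.noise_sd}")
        lo, hi = self.x_domain
        if not lo < hi:
            raise SpecValidationError("x_domain", f"lower must be < upper, got {self.x_domain}")
        if self.x_scale not in (LOG10, IDENTITY):
            raise SpecValidationError("x_scale", f"must be log10 or identity, got {self.x_scale!r}")
        if self.x_scale == LOG10 and lo <= 0:
            raise SpecValidationError("x_domain", "lower bound must be > 0 under log10")
        if self.form in ("segmented", "logistic"):
            tlo, thi = self.transformed_domain()
            bp = self.params["bp"]
            if not tlo < bp < thi:
                raise SpecValidationError(
                    "params", f"bp={bp} must lie strictly inside the transformed domain ({tlo}, {thi})"
                )

    def transformed_domain(self) -> tuple[float, float]:
        lo, hi = self.x_domain
        if self.x_scale == LOG10:
            return (float(np.log10(lo)), float(np.log10(hi)))
        return (float(lo), float(hi))


def generate_gradient(spec: GeneratorSpec) -> GradientDataset:
    """Draw one gradient dataset; deterministic given the spec's seed.

    x is uniform on the transformed scale of ``x_domain``; y is the chosen form
    evaluated at x plus N(0, noise_sd) noise.  The true parameters are attached
    as ``dataset.truth``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    tlo, thi = spec.transformed_domain()
    x = rng.uniform(tlo, thi, spec.n)
    y = predict(spec.form, spec.params, x)
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, spec.n)
    return GradientDataset(
        x=x,
        y=y,
        x_name=spec.x_name,
        y_name=spec.y_name,
        x_transform=spec.x_scale,
        y_transform=spec.y_transform,
        truth={"form": spec.form, "params": dict(spec.params),
               "noise_sd": spec.noise_sd, "seed": spec.seed},
    )


# ---------------------------------------------------------------------------
# waterbody populations

#: Placeholder per-type metric distributions: ("lognormal", mean of ln X, sd of
#: ln X) or ("normal", mean, sd).  Orderings: TN ponds highest; TP ponds and
#: wetlands high (ponds most variable), lakes low; chl a ponds ~ lakes with
#: wetlands lower but most variable; pH ponds lowest.
DEFAULT_METRIC_DISTRIBUTIONS: dict[str, dict[str, tuple[str, float, float]]] = {
    "pond": {
        "TP": ("lognormal", 4.6, 1.2),     # ~100 ug/L median
        "TN": ("lognormal", 7.0, 0.8),     # ~1100 ug/L median
        "chl_a": ("lognormal", 2.3, 1.0),  # ~10 ug/L median
        "pH": ("normal", 7.0, 0.8),
    },
    "lake": {
        "TP": ("lognormal", 3.0, 0.8),
        "TN": ("lognormal", 6.0, 0.6),
        "chl_a": ("lognormal", 2.1, 0.9),
        "pH": ("normal", 7.8, 0.5),
    },
    "wetland": {
        "TP": ("lognormal", 4.5, 1.0),
        "TN": ("lognormal", 6.3, 0.7),
        "chl_a": ("lognormal", 1.2, 1.4),
        "pH": ("normal", 7.4, 0.7),
    },
}

#: Morphometry sampling ranges per type: area (ha, log-uniform), depth (m,
#: log-uniform), vegetation cover (%, uniform).  Wetlands are < 1 m deep and
#: heavily vegetated; lakes are larger and deeper than ponds.
DEFAULT_MORPHOMETRY = {
    "pond": {"area": (1e-3, 5.0), "depth": (0.2, 5.0), "veg": (0.0, 30.0)},
    "lake": {"area": (5.0, 1e3), "depth": (2.0, 50.0), "veg": (0.0, 10.0)},
    "wetland": {"area": (1e-3, 100.0), "depth": (0.05, 1.0), "veg": (30.0, 100.0)},
}


@dataclass
class PopulationSpec:
    """Recipe for a synthetic waterbody population."""

    n_per_type: dict[str, int] = field(
        default_factory=lambda: {"pond": 600, "lake": 600, "wetland": 400}
    )
    metric_distributions: dict[str, dict[str, tuple[str, float, float]]] = field(
        default_factory=lambda: {t: dict(d) for t, d in DEFAULT_METRIC_DISTRIBUTIONS.items()}
    )
    morphometry: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {t: dict(d) for t, d in DEFAULT_MORPHOMETRY.items()}
    )
    p_permanent: float = 0.74
    p_constructed: float = 0.65
    seed: int = 0

    def validate(self) -> None:
        for frac_name in ("p_permanent", "p_constructed"):
            value = getattr(self, frac_name)
            if not 0.0 <= value <= 1.0:
                raise SpecValidationError(frac_name, f"must be in [0, 1], got {value}")
        for label, count in self.n_per_type.items():
            if count < 0:
                raise SpecValidationError("n_per_type", f"{label}: must be >= 0, got {count}")
            if count > 0 and label not in self.metric_distributions:
                raise SpecValidationError("metric_distributions", f"no distributions for type {label!r}")
            if count > 0 and label not in self.morphometry:
                raise SpecValidationError("morphometry", f"no ranges for type {label!r}")
        for label, dists in self.metric_distributions.items():
            for metric, (family, _loc, scale) in dists.items():
                if family not in ("lognormal", "normal"):
                    raise SpecValidationError(
                        "metric_distributions", f"{label}/{metric}: unknown family {family!r}"
                    )
                if scale <= 0:
                    raise SpecValidationError(
                        "metric_distributions", f"{label}/{metric}: scale must be > 0, got {scale}"
                    )


def generate_population(spec: PopulationSpec) -> list[WaterbodyRecord]:
    """Draw waterbody records per type; deterministic given the spec's seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    records: list[WaterbodyRecord] = []
    for label in sorted(spec.n_per_type):
        count = spec.n_per_type[label]
        if count == 0:
            continue
        morph = spec.morphometry[label]
        area = 10.0 ** rng.uniform(*np.log10(morph["area"]), count)
        depth = 10.0 ** rng.uniform(*np.log10(morph["depth"]), count)
        veg = rng.uniform(*morph["veg"], count)
        permanent = rng.random(count) < spec.p_permanent
        constructed = rng.random(count) < spec.p_constructed
        draws: dict[str, np.ndarray] = {}
        for metric in sorted(spec.metric_distributions[label]):
            family, loc, scale = spec.metric_distributions[label][metric]
            if family == "lognormal":
                draws[metric] = rng.lognormal(loc, scale, count)
            else:
                draws[metric] = rng.normal(loc, scale, count)
        for i in range(count):
            records.append(
                WaterbodyRecord(
                    id=f"{label}_{i:04d}",
                    surface_area_ha=float(area[i]),
                    max_depth_m=float(depth[i]),
                    emergent_veg_pct=float(np.clip(veg[i], 0.0, 100.0)),
                    source_label=label,
                    hydroperiod="permanent" if permanent[i] else "temporary",
                    origin="constructed" if constructed[i] else "natural",
                    metrics={m: float(v[i]) for m, v in draws.items()},
                )
            )
    return records


def population_to_frame(records: list[WaterbodyRecord]) -> pd.DataFrame:
    """Flatten records to a table (one metric column each)."""
    rows = []
    for rec in records:
        row = {
            "id": rec.id,
            "surface_area_ha": rec.surface_area_ha,
            "max_depth_m": rec.max_depth_m,
            "emergent_veg_pct": rec.emergent_veg_pct,
            "type": rec.source_label,
            "hydroperiod": rec.hydroperiod,
            "origin": rec.origin,
        }
        row.update(rec.metrics)
        rows.append(row)
    return pd.DataFrame(rows)


def _write_sidecar(path: Path, spec) -> None:
    sidecar = path.with_suffix(path.suffix + ".spec.yaml")
    payload = asdict(spec)
    payload["spec_type"] = type(spec).__name__
    sidecar.write_text(yaml.safe_dump(payload, sort_keys=True))


def write_gradient_csv(dataset: GradientDataset, path, spec: GeneratorSpec | None = None) -> None:
    """Write (x, y) pairs on the transformed scale; sidecar YAML records the spec."""
    path = Path(path)
    pd.DataFrame({dataset.x_name: dataset.x, dataset.y_name: dataset.y}).to_csv(path, index=False)
    if spec is not None:
        _write_sidecar(path, spec)


def write_population_csv(records: list[WaterbodyRecord], path, spec: PopulationSpec | None = None) -> None:
    path = Path(path)
    population_to_frame(records).to_csv(path, index=False)
    if spec is not None:
        _write_sidecar(path, spec)
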