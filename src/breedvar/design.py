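"""Trial design and simulation parameters for a mutagenesis field experiment.

The design emulates a two-variety cowpea mutation-breeding trial: batches of
300 dry seeds per treatment exposed to gamma-ray doses (100-1000 Gy, G1-G10),
sodium-azide concentrations (0.01-0.1 %, S1-S10) and their pairwise
combinations (G1+S1..G10+S10), grown in a randomized complete block design
with 30 replications and phenotyped for ten quantitative traits over
generations M1-M4.

`SimParams` encodes the statistical ground truth the downstream analyses
assume: per-trait genotypic variance among lines, plot-error variance,
per-treatment mean shifts, a linear path structure generating plant yield
from its component traits, and a logistic germination decline with dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Mapping, Sequence

from .reference import GOMATI_M2_MEANS, TRAITS

#: Canonical trait codes, in table order.
TRAIT_CODES = TRAITS

TRAIT_NAMES = {
    "PH": "plant height (cm)",
    "DF": "days to flowering",
    "DM": "days to maturity",
    "PPP": "pods per plant",
    "BPP": "branches per plant",
    "SPP": "seeds per pod",
    "SW": "100-seed weight (g)",
    "PL": "pod length (cm)",
    "PY": "plant yield (g)",
    "HI": "harvest index (%)",
}

YIELD_TRAIT = "PY"

#: Yield-component traits entering the path decomposition (plant height and
#: the two phenology traits have negligible direct effects and are excluded).
PATH_PREDICTORS = ("PPP", "BPP", "SPP", "SW", "PL", "HI")

#: Scale on which a sodium-azide concentration (in %) is mapped onto a
#: gamma-equivalent dose: 0.01 % SA ~ 100 Gy-equivalent.
SA_DOSE_SCALE = 1.0e4


@dataclass(frozen=True)
class Treatment:
    """One mutagen treatment: a label, a gamma dose (Gy) and an SA dose (%)."""

    label: str
    gamma_gy: float = 0.0
    sa_percent: float = 0.0

    def __post_init__(self) -> None:
        if self.gamma_gy < 0 or self.sa_percent < 0:
            raise ValueError(f"treatment {self.label!r}: doses must be >= 0")

    @property
    def is_control(self) -> bool:
        return self.gamma_gy == 0 and self.sa_percent == 0


def composite_dose(
    treatment: Treatment,
    sa_weight: float = 1.0,
    combine: str = "max",
) -> float:
    """Map a (gamma, SA) treatment onto a single Gy-equivalent severity.

    The SA concentration is rescaled by :data:`SA_DOSE_SCALE` and weighted by
    ``sa_weight``.  With ``combine="max"`` (the default) the two mutagens act
    as limiting factors — the harsher one sets the severity — which places
    each series' germination-based exclusion boundary at the same dose index
    and reproduces the retained-population structure of the trial.
    ``combine="sum"`` gives the additive composite instead.
    """
    sa_equiv = sa_weight * treatment.sa_percent * SA_DOSE_SCALE
    if combine == "max":
        return max(treatment.gamma_gy, sa_equiv)
    if combine == "sum":
        return treatment.gamma_gy + sa_equiv
    raise ValueError(f"unknown dose combiner {combine!r} (use 'max' or 'sum')")


def _check_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"parameter {name!r} must be finite, got {value!r}")


@dataclass(frozen=True)
class TrialDesign:
    """Structural layout of the trial (who is grown, how often, what is measured)."""

    varieties: tuple[str, ...] = ("Gomati VU-89", "Pusa-578")
    treatments: tuple[Treatment, ...] = ()
    seeds_per_treatment: int = 300
    replications: int = 30
    lines_per_treatment: int = 60
    generations: tuple[str, ...] = ("M1", "M2", "M3", "M4")
    traits: tuple[str, ...] = TRAIT_CODES

    def __post_init__(self) -> None:
        if not self.treatments:
            object.__setattr__(self, "treatments", default_treatments())
        controls = [t for t in self.treatments if t.is_control]
        if len(controls) != 1:
            raise ValueError(
                f"design must contain exactly one control treatment, found {len(controls)}"
            )
        if self.replications < 2:
            raise ValueError("replications must be >= 2")
        if self.lines_per_treatment < 2:
            raise ValueError("lines_per_treatment must be >= 2")
        if self.seeds_per_treatment < 1:
            raise ValueError("seeds_per_treatment must be >= 1")
        labels = [t.label for t in self.treatments]
        if len(set(labels)) != len(labels):
            raise ValueError("treatment labels must be unique")
        if len(set(self.traits)) != len(self.traits):
            raise ValueError("trait names must be unique")
        if not self.varieties or not self.generations:
            raise ValueError("varieties and generations must be non-empty")

    @property
    def control_label(self) -> str:
        return next(t.label for t in self.treatments if t.is_control)

    def treatment(self, label: str) -> Treatment:
        for t in self.treatments:
            if t.label == label:
                return t
        raise KeyError(f"no treatment labelled {label!r}")

    def total_seeds(self, treatments: Sequence[str] | None = None) -> int:
        """Seeds sown across varieties for the given (default: all) treatments."""
        n = len(self.treatments) if treatments is None else len(treatments)
        return self.seeds_per_treatment * n * len(self.varieties)


def default_treatments() -> tuple[Treatment, ...]:
    """Control + G1-G10 + S1-S10 + G1+S1..G10+S10 (31 treatments)."""
    out = [Treatment("C")]
    for i in range(1, 11):
        out.append(Treatment(f"G{i}", gamma_gy=100.0 * i))
    for i in range(1, 11):
        out.append(Treatment(f"S{i}", sa_percent=0.01 * i))
    for i in range(1, 11):
        out.append(Treatment(f"G{i}+S{i}", gamma_gy=100.0 * i, sa_percent=0.01 * i))
    return tuple(out)


def _default_means() -> dict[str, float]:
    return {t: float(GOMATI_M2_MEANS.loc["C", t]) for t in TRAIT_CODES}


def _default_shifts() -> dict[str, dict[str, float]]:
    # Treatment-mean shifts taken from the published M2 mean matrix
    # (treated mean minus control mean); treatments outside it shift by 0.
    shifts: dict[str, dict[str, float]] = {}
    control = GOMATI_M2_MEANS.loc["C"]
    for pop in GOMATI_M2_MEANS.index:
        if pop == "C":
            continue
        shifts[pop] = {t: float(GOMATI_M2_MEANS.loc[pop, t] - control[t]) for t in TRAIT_CODES}
    return shifts


def _default_sigma2_g() -> dict[str, float]:
    # Genotypic SD among lines defaults to 5 % of the trait mean.
    return {t: (0.05 * m) ** 2 for t, m in _default_means().items()}


def _default_sigma2_e() -> dict[str, float]:
    # Plot-error variance a quarter of the genotypic variance: plot-basis
    # heritability of 0.8, in line with the high h2 values the trial reports.
    return {t: v / 4.0 for t, v in _default_sigma2_g().items()}


def _default_path_coefficients() -> dict[str, float]:
    return {"SW": 0.6, "SPP": 0.4, "PPP": 0.2, "HI": 0.15, "BPP": 0.1, "PL": -0.05}


@dataclass(frozen=True)
class SimParams:
    """Ground-truth parameters of the synthetic trial.

    ``trait_means`` are control-population grand means; ``treatment_shifts``
    maps treatment label -> trait -> additive mean shift (missing entries
    shift by zero).  ``sigma2_g`` / ``sigma2_e`` are per-trait genotypic and
    plot-error variances.  Plant yield is generated on the standardized scale
    as sum(b_t * z_t) + residual over the genotypic component scores z_t,
    then back-scaled by sqrt(sigma2_g[PY]).  Germination declines
    logistically with the composite dose, anchored so dose 0 gives the
    baseline rate ``germination_baseline``.
    """

    trait_means: Mapping[str, float] = field(default_factory=_default_means)
    treatment_shifts: Mapping[str, Mapping[str, float]] = field(default_factory=_default_shifts)
    sigma2_g: Mapping[str, float] = field(default_factory=_default_sigma2_g)
    sigma2_e: Mapping[str, float] = field(default_factory=_default_sigma2_e)
    path_coefficients: Mapping[str, float] = field(default_factory=_default_path_coefficients)
    yield_residual_sd: float = 0.6364
    germination_baseline: float = 0.9
    germination_slope: float = 0.012
    germination_d50: float = 435.0
    sa_weight: float = 1.0
    dose_combine: str = "max"

    def __post_init__(self) -> None:
        for name in ("yield_residual_sd", "germination_baseline",
                     "germination_slope", "germination_d50", "sa_weight"):
            _check_finite(name, float(getattr(self, name)))
        if not 0 < self.germination_baseline <= 1:
            raise ValueError("germination_baseline must lie in (0, 1]")
        if self.germination_slope <= 0:
            raise ValueError("germination_slope must be > 0")
        if self.yield_residual_sd < 0:
            raise ValueError("yield_residual_sd must be >= 0")
        for mapping, label in ((self.sigma2_g, "sigma2_g"), (self.sigma2_e, "sigma2_e")):
            for t, v in mapping.items():
                _check_finite(f"{label}[{t}]", float(v))
                if v < 0:
                    raise ValueError(f"{label}[{t}] must be >= 0")
        for t, v in self.trait_means.items():
            _check_finite(f"trait_means[{t}]", float(v))
        composite_dose(Treatment("C"), self.sa_weight, self.dose_combine)  # validates combiner

    def shift(self, treatment_label: str, trait: str) -> float:
        return float(self.treatment_shifts.get(treatment_label, {}).get(trait, 0.0))

    def germination_rate(self, dose: float) -> float:
        """Expected germination fraction at a composite dose (Gy-equivalent)."""
        s, d50 = self.germination_slope, self.germination_d50
        logistic = lambda x: 1.0 / (1.0 + math.exp(min(700.0, x)))
        raw = logistic(s * (dose - d50))
        return self.germination_baseline * raw / logistic(-s * d50)


def _from_dict(cls, data: Mapping, context: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown {context} keys: {sorted(unknown)}")
    return cls(**data)


def design_from_dict(data: Mapping) -> TrialDesign:
    """Build a :class:`TrialDesign` from a config mapping; unknown keys rejected."""
    data = dict(data)
    if "treatments" in data:
        data["treatments"] = tuple(
            Treatment(**t) if isinstance(t, Mapping) else Treatment(*t)
            for t in data["treatments"]
        )
    for key in ("varieties", "generations", "traits"):
        if key in data:
            data[key] = tuple(data[key])
    return _from_dict(TrialDesign, data, "design")


def params_from_dict(data: Mapping) -> SimParams:
    """Build :class:`SimParams` from a config mapping; unknown keys rejected."""
    return _from_dict(SimParams, dict(data), "simulation-parameter")
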