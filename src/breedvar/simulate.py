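"""Seeded synthetic-trial generator.

Produces germination counts per treatment and balanced replicate-level trait
tables across generations with known ground truth: line (genotypic) effects
drawn once and persisting across generations, plot errors redrawn each
season, treatment mean shifts, and plant yield assembled from its component
traits through a linear path structure.

All randomness flows from one integer seed through ``numpy``'s
``SeedSequence`` spawning; no global state is touched.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import SimParams, TrialDesign, YIELD_TRAIT, composite_dose

#: Column order of the long-format trait table.
TRAIT_TABLE_COLUMNS = (
    "variety", "generation", "treatment", "line", "replicate", "trait", "value",
)


@dataclass(frozen=True)
class SelectionRule:
    """Truncation-selection rule applied between generations.

    ``n=None`` keeps every line (no selection).  Selection first applies when
    advancing *from* ``start_generation``; earlier transitions keep all lines.
    The untreated check is never selected on phenotype: unless
    ``include_control`` is set it is advanced as a deterministic unbiased
    subsample of ``n`` lines, keeping later generations balanced.
    """

    trait: str = YIELD_TRAIT
    n: int | None = 30
    direction: str = "max"
    start_generation: str = "M2"
    include_control: bool = False

    def __post_init__(self) -> None:
        if self.n is not None and self.n < 1:
            raise ValueError("selection n must be >= 1 (or None to keep all)")
        if self.direction not in ("max", "min"):
            raise ValueError("direction must be 'max' or 'min'")


def simulate_germination(
    design: TrialDesign, params: SimParams, seed: int
) -> pd.DataFrame:
    """Simulate seeds germinated per treatment.

    Germinated counts are Binomial(seeds sown, p) with p the logistic
    dose-response of :meth:`SimParams.germination_rate` at each treatment's
    composite dose; the control sits at the baseline rate.  Deterministic
    given ``seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for t in design.treatments:
        dose = composite_dose(t, params.sa_weight, params.dose_combine)
        p = params.germination_rate(dose)
        sown = design.seeds_per_treatment
        germinated = int(rng.binomial(sown, p))
        rows.append(
            {
                "treatment": t.label,
                "sown": sown,
                "germinated": germinated,
                "germination_pct": 100.0 * germinated / sown,
            }
        )
    return pd.DataFrame(rows)


def apply_dose_exclusion(
    germination: pd.DataFrame,
    control_label: str = "C",
    threshold_fraction: float = 0.5,
) -> list[str]:
    """Treatments retained after the germination-reduction exclusion rule.

    A treatment is retained when its germination percentage is at least
    ``threshold_fraction`` of the control's (doses causing *more* than a
    50 % reduction are dropped, so the boundary case is kept).  The control
    is always retained; input order is preserved.
    """
    labels = list(germination["treatment"])
    if control_label not in labels:
        raise ValueError(f"control treatment {control_label!r} not present in germination table")
    pct = dict(zip(germination["treatment"], germination["germination_pct"]))
    cutoff = threshold_fraction * pct[control_label]
    return [
        lab for lab in labels
        if lab == control_label or pct[lab] >= cutoff
    ]


def _line_ids(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"L{i:0{width}d}" for i in range(1, n + 1)]


def _draw_line_effects(
    design: TrialDesign,
    params: SimParams,
    rng: np.random.Generator,
    treatments: Sequence[str],
) -> dict[tuple[str, str], np.ndarray]:
    """Genotypic effects per (variety, treatment): array (n_lines, n_traits).

    Component traits get independent Normal(0, sigma2_g) effects; the yield
    trait's genotypic score is the path-weighted sum of the standardized
    component scores plus an independent residual, back-scaled to yield units.
    """
    traits = list(design.traits)
    n = design.lines_per_treatment
    sig_g = np.array([math.sqrt(params.sigma2_g.get(t, 0.0)) for t in traits])
    yield_idx = traits.index(YIELD_TRAIT) if YIELD_TRAIT in traits else None
    out: dict[tuple[str, str], np.ndarray] = {}
    for variety in design.varieties:
        for label in treatments:
            g = rng.normal(0.0, 1.0, size=(n, len(traits))) * sig_g
            if yield_idx is not None:
                z = np.zeros(n)
                for comp, b in params.path_coefficients.items():
                    if comp in traits and sig_g[traits.index(comp)] > 0:
                        z += b * g[:, traits.index(comp)] / sig_g[traits.index(comp)]
                z += params.yield_residual_sd * rng.normal(0.0, 1.0, size=n)
                g[:, yield_idx] = sig_g[yield_idx] * z
            out[(variety, label)] = g
    return out


def _build_generation(
    design: TrialDesign,
    params: SimParams,
    generation: str,
    effects: Mapping[tuple[str, str], np.ndarray],
    lines: Mapping[tuple[str, str], Sequence[int]],
    rng: np.random.Generator,
) -> pd.DataFrame:
    traits = list(design.traits)
    r = design.replications
    sig_e = np.array([math.sqrt(params.sigma2_e.get(t, 0.0)) for t in traits])
    all_ids = _line_ids(design.lines_per_treatment)
    frames = []
    for variety in design.varieties:
        for label in sorted({lab for (v, lab) in lines if v == variety}):
            idx = np.asarray(lines[(variety, label)], dtype=int)
            g = effects[(variety, label)][idx]  # (n_sel, n_traits)
            base = np.array(
                [params.trait_means.get(t, 0.0) + params.shift(label, t) for t in traits]
            )
            errors = rng.normal(0.0, 1.0, size=(len(idx), r, len(traits))) * sig_e
            values = base + g[:, None, :] + errors
            n_sel = len(idx)
            frames.append(
                pd.DataFrame(
                    {
                        "variety": variety,
                        "generation": generation,
                        "treatment": label,
                        "line": np.repeat([all_ids[i] for i in idx], r * len(traits)),
                        "replicate": np.tile(np.repeat(np.arange(1, r + 1), len(traits)), n_sel),
                        "trait": np.tile(traits, n_sel * r),
                        "value": values.reshape(-1),
                    }
                )
            )
    table = pd.concat(frames, ignore_index=True)
    return table[list(TRAIT_TABLE_COLUMNS)]


def simulate_trait_table(
    design: TrialDesign,
    params: SimParams,
    generation: str,
    seed: int,
    treatments: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Simulate one generation's balanced replicate-level trait table.

    value(line, rep, trait) = grand mean + treatment shift + line effect +
    plot error, with line effects ~ Normal(0, sigma2_g) and plot errors ~
    Normal(0, sigma2_e).  Every (line, replicate, trait) cell is present;
    identical inputs give bit-identical tables.
    """
    if treatments is None:
        treatments = [t.label for t in design.treatments]
    else:
        for lab in treatments:
            design.treatment(lab)  # raises on unknown labels
    ss = np.random.SeedSequence(seed)
    eff_rng, err_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    effects = _draw_line_effects(design, params, eff_rng, treatments)
    lines = {
        key: list(range(design.lines_per_treatment)) for key in effects
    }
    return _build_generation(design, params, generation, effects, lines, err_rng)


def simulate_generations(
    design: TrialDesign,
    params: SimParams,
    selection_rule: SelectionRule | None = None,
    seed: int = 0,
    treatments: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Simulate all generations of the trial with selection between them.

    Line (genotypic) effects are drawn once and persist across generations —
    the heritable component — while plot errors are redrawn each season.
    From ``selection_rule.start_generation`` onwards, each generation's line
    set is the truncation-selected subset of the previous one's, ranked by
    observed (phenotypic) line means of the selection trait.
    """
    rule = selection_rule or SelectionRule()
    if treatments is None:
        treatments = [t.label for t in design.treatments]
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(1 + len(design.generations))
    effects = _draw_line_effects(
        design, params, np.random.default_rng(streams[0]), treatments
    )
    lines = {key: list(range(design.lines_per_treatment)) for key in effects}
    control = design.control_label
    selecting = False
    tables = []
    for gen, stream in zip(design.generations, streams[1:]):
        table = _build_generation(
            design, params, gen, effects, lines, np.random.default_rng(stream)
        )
        tables.append(table)
        if rule.n is not None and gen == rule.start_generation:
            selecting = True
        if selecting and rule.n is not None:
            lines = _select_lines(table, lines, rule, control, design)
    return pd.concat(tables, ignore_index=True)


def _select_lines(
    table: pd.DataFrame,
    lines: Mapping[tuple[str, str], Sequence[int]],
    rule: SelectionRule,
    control_label: str,
    design: TrialDesign,
) -> dict[tuple[str, str], list[int]]:
    all_ids = _line_ids(design.lines_per_treatment)
    id_to_idx = {lid: i for i, lid in enumerate(all_ids)}
    sub = table[table["trait"] == rule.trait]
    if sub.empty:
        raise ValueError(f"selection trait {rule.trait!r} absent from simulated table")
    means = sub.groupby(["variety", "treatment", "line"], sort=True)["value"].mean()
    out: dict[tuple[str, str], list[int]] = {}
    for key, idx in lines.items():
        variety, label = key
        if label == control_label and not rule.include_control:
            # the check is re-sown at the same plot count but without
            # phenotypic selection; control lines are exchangeable, so the
            # first n ids are an unbiased (and deterministic) subsample
            out[key] = sorted(idx)[: min(rule.n, len(idx))]
            continue
        if rule.n > len(idx):
            raise ValueError(
                f"selection n={rule.n} exceeds the {len(idx)} lines available "
                f"for ({variety!r}, {label!r})"
            )
        cell = means.loc[(variety, label)]
        ascending = rule.direction == "min"
        # ties broken by line id (the secondary sort key) for determinism
        ranked = cell.sort_index().sort_values(ascending=ascending, kind="stable")
        kept = list(ranked.index[: rule.n])
        out[key] = sorted(id_to_idx[lid] for lid in kept)
    return out


def true_line_effects(
    design: TrialDesign,
    params: SimParams,
    seed: int,
    treatments: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Ground-truth genotypic effects, as drawn by :func:`simulate_generations`
    (and by :func:`simulate_trait_table`) for the same seed.

    Returns a long frame (variety, treatment, line, trait, effect) — useful
    for checking that selection actually captures superior genotypes.
    """
    if treatments is None:
        treatments = [t.label for t in design.treatments]
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1 + len(design.generations))[0])
    effects = _draw_line_effects(design, params, rng, treatments)
    ids = _line_ids(design.lines_per_treatment)
    rows = []
    for (variety, label), g in effects.items():
        for i, lid in enumerate(ids):
            for j, trait in enumerate(design.traits):
                rows.append((variety, label, lid, trait, g[i, j]))
    return pd.DataFrame(
        rows, columns=["variety", "treatment", "line", "trait", "effect"]
    )
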