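"""Truncation selection of high-yielding lines and genetic-gain accounting.

Genetic gain is operationalized as the percent yield advantage of a treated
population over the same-generation untreated control,

    gain% = 100 * (treatment mean - control mean) / control mean,

the only definition consistent with the trial's printed per-generation gain
figures; the between-generation improvement is the difference of gains,
delta = gain(later) - gain(earlier).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionResult:
    """Selected lines per treatment, ordered by descending trait mean."""

    variety: str
    generation: str
    trait: str
    n_requested: int
    selected: dict[str, tuple[str, ...]]  # treatment -> ordered line ids
    line_means: pd.Series  # (treatment, line) -> mean trait value


def select_top(
    table: pd.DataFrame,
    variety: str,
    generation: str,
    trait: str = "PY",
    n: int = 30,
    treatments: list[str] | None = None,
) -> SelectionResult:
    """Top-n lines per treatment, ranked by mean trait value over replicates.

    Ties break by line id.  If a treatment holds fewer than ``n`` lines, all
    of them are returned with a logged warning.
    """
    if n <= 0:
        raise ValueError(f"selection size n must be positive, got {n}")
    sub = table[
        (table["variety"] == variety)
        & (table["generation"] == generation)
        & (table["trait"] == trait)
    ]
    if sub.empty:
        raise ValueError(
            f"no {trait!r} observations for ({variety!r}, {generation!r})"
        )
    if treatments is None:
        treatments = list(dict.fromkeys(sub["treatment"]))
    else:
        missing = [t for t in treatments if t not in set(sub["treatment"])]
        if missing:
            raise ValueError(f"treatments absent from table: {missing}")
    means = sub.groupby(["treatment", "line"])["value"].mean()
    selected = {}
    for lab in treatments:
        cell = means.loc[lab]
        if len(cell) < n:
            logger.warning(
                "treatment %r has only %d lines (< n=%d); keeping all",
                lab, len(cell), n,
            )
        ranked = cell.sort_index().sort_values(ascending=False, kind="stable")
        selected[lab] = tuple(ranked.index[:n])
    return SelectionResult(
        variety=variety,
        generation=generation,
        trait=trait,
        n_requested=n,
        selected=selected,
        line_means=means,
    )


@dataclass(frozen=True)
class GainReport:
    """Per-treatment genetic gain relative to the same-generation control."""

    variety: str
    generation: str
    control_label: str
    trait: str
    table: pd.DataFrame  # columns: mean, control_mean, gain_pct; index: treatment

    @property
    def gains(self) -> pd.Series:
        return self.table["gain_pct"]


def genetic_gain(
    data: pd.DataFrame | pd.Series,
    variety: str = "",
    generation: str = "",
    control_label: str = "C",
    trait: str = "PY",
) -> GainReport:
    """Genetic gain per treatment.

    ``data`` is either a long-format trait table (means are computed from
    it) or a Series of per-treatment means — published summary rows can be
    fed directly.
    """
    if isinstance(data, pd.Series):
        means = data.astype(float)
    else:
        sub = data[
            (data["variety"] == variety)
            & (data["generation"] == generation)
            & (data["trait"] == trait)
        ]
        if sub.empty:
            raise ValueError(
                f"no {trait!r} observations for ({variety!r}, {generation!r})"
            )
        means = sub.groupby("treatment")["value"].mean()
        means = means.loc[list(dict.fromkeys(sub["treatment"]))]
    if control_label not in means.index:
        raise ValueError(f"control {control_label!r} missing from means")
    control = float(means[control_label])
    if control <= 0:
        raise ValueError(f"control mean must be > 0, got {control}")
    out = pd.DataFrame(
        {
            "mean": means,
            "control_mean": control,
            "gain_pct": 100.0 * (means - control) / control,
        }
    )
    return GainReport(
        variety=variety, generation=generation, control_label=control_label,
        trait=trait, table=out,
    )


def gain_delta(earlier: GainReport, later: GainReport) -> pd.DataFrame:
    """Change in gain between two generations, per treatment.

    Treatments present in both reports must match exactly; the result also
    carries the argmax treatment (largest improvement) as ``.attrs["argmax"]``.
    """
    if earlier.variety != later.variety:
        raise ValueError(
            f"variety mismatch: {earlier.variety!r} vs {later.variety!r}"
        )
    common = [t for t in later.table.index if t != later.control_label]
    missing = [t for t in common if t not in earlier.table.index]
    if missing:
        raise ValueError(f"treatments missing from the earlier report: {missing}")
    out = pd.DataFrame(
        {
            "gain_earlier_pct": earlier.gains.loc[common],
            "gain_later_pct": later.gains.loc[common],
        }
    )
    out["delta_pct"] = out["gain_later_pct"] - out["gain_earlier_pct"]
    out.attrs["argmax"] = str(out["delta_pct"].idxmax())
    return out
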