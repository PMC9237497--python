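"""Variance components and genetic parameters from one-way ANOVA among lines.

For each (variety, generation, treatment, trait) cell the observations are a
balanced one-way layout: lines within the treatment, each with r replicate
plots.  The among-line mean square (MSG) and the pooled within-line error
mean square (MSE) give the moment estimators

    sigma2_g = (MSG - MSE) / r          genotypic variance
    sigma2_p = sigma2_g + MSE           phenotypic variance (plot basis)
    GCV %    = 100 * sqrt(sigma2_g) / mean
    h2 %     = 100 * sigma2_g / sigma2_p
    GA %     = 100 * k * sigma_p * (h2/100) / mean
             = k * GCV% * sqrt(h2%/100)     (algebraic identity)

with k the standardized selection differential (2.64 for 1 % selection
intensity).  Negative moment estimates of sigma2_g are truncated to zero
with a logged warning, the conventional resolution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dmrt import dmrt_letters

logger = logging.getLogger(__name__)

#: Standardized selection differential at 1 % selection intensity.
DEFAULT_K = 2.64


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA among lines: mean squares, df, F and its p-value."""

    msg: float
    mse: float
    df_g: int
    df_e: int
    f: float
    p: float
    r: int

    @property
    def f_defined(self) -> bool:
        return math.isfinite(self.f)


@dataclass(frozen=True)
class GeneticParams:
    """Per-cell genetic parameters in the Allard notation."""

    mean: float
    se_mean: float
    sigma2_g: float
    sigma2_p: float
    gcv_pct: float
    h2_pct: float
    ga_pct: float
    k: float = DEFAULT_K


def _cell(
    table: pd.DataFrame, variety: str, generation: str, treatment: str, trait: str
) -> pd.DataFrame:
    mask = (
        (table["variety"] == variety)
        & (table["generation"] == generation)
        & (table["treatment"] == treatment)
        & (table["trait"] == trait)
    )
    cell = table.loc[mask]
    if cell.empty:
        raise ValueError(
            f"no observations for ({variety!r}, {generation!r}, {treatment!r}, {trait!r})"
        )
    return cell


def anova_lines(
    table: pd.DataFrame, variety: str, generation: str, treatment: str, trait: str
) -> AnovaResult:
    """Balanced one-way ANOVA among the lines of one treatment cell.

    MSG = r * sum((line mean - grand mean)^2) / (n_lines - 1); MSE pools the
    within-line replicate variation.  Requires >= 2 lines with equal
    replicate counts >= 2; unbalanced cells raise an error naming the
    offending lines.
    """
    cell = _cell(table, variety, generation, treatment, trait)
    counts = cell.groupby("line")["value"].count()
    if len(counts) < 2:
        raise ValueError(
            f"ANOVA needs >= 2 lines; cell ({variety!r}, {generation!r}, "
            f"{treatment!r}, {trait!r}) has {len(counts)}"
        )
    r = int(counts.iloc[0])
    if counts.nunique() > 1:
        modal = int(counts.mode().iloc[0])
        odd = sorted(counts.index[counts != modal])
        raise ValueError(
            f"unbalanced cell: lines {odd} have replicate counts differing "
            f"from the modal {modal}"
        )
    if r < 2:
        raise ValueError("ANOVA needs >= 2 replicates per line")
    line_means = cell.groupby("line")["value"].mean()
    grand = float(cell["value"].mean())
    df_g = len(line_means) - 1
    df_e = len(line_means) * (r - 1)
    ssg = r * float(((line_means - grand) ** 2).sum())
    sse = float(((cell["value"] - cell["line"].map(line_means)) ** 2).sum())
    msg_, mse = ssg / df_g, sse / df_e
    if mse > 0:
        f = msg_ / mse
        p = float(stats.f.sf(f, df_g, df_e))
    else:
        f, p = float("nan"), float("nan")
    return AnovaResult(msg=msg_, mse=mse, df_g=df_g, df_e=df_e, f=f, p=p, r=r)


def genetic_advance_percent(
    gcv_pct: float, h2_pct: float, k: float = DEFAULT_K
) -> float:
    """Genetic advance as percent of the mean: k * GCV% * sqrt(h2%/100)."""
    if not 0 <= h2_pct <= 100:
        raise ValueError(f"h2_pct must lie in [0, 100], got {h2_pct}")
    if gcv_pct < 0:
        raise ValueError("gcv_pct must be >= 0")
    return k * gcv_pct * math.sqrt(h2_pct / 100.0)


def genetic_parameters(
    anova: AnovaResult,
    grand_mean: float,
    k: float = DEFAULT_K,
    se_mean: float = float("nan"),
) -> GeneticParams:
    """Genetic parameters from ANOVA mean squares and the cell grand mean.

    A negative raw (MSG - MSE)/r is truncated to zero (logged, not raised).
    """
    if grand_mean <= 0:
        raise ValueError(f"grand mean must be > 0, got {grand_mean}")
    raw = (anova.msg - anova.mse) / anova.r
    sigma2_g = max(0.0, raw)
    if raw < 0:
        logger.warning(
            "negative genotypic variance estimate %.6g truncated to 0", raw
        )
    sigma2_p = sigma2_g + anova.mse
    gcv = 100.0 * math.sqrt(sigma2_g) / grand_mean
    h2 = 100.0 * sigma2_g / sigma2_p if sigma2_p > 0 else 0.0
    ga = 100.0 * k * math.sqrt(sigma2_p) * (h2 / 100.0) / grand_mean
    return GeneticParams(
        mean=grand_mean,
        se_mean=se_mean,
        sigma2_g=sigma2_g,
        sigma2_p=sigma2_p,
        gcv_pct=gcv,
        h2_pct=h2,
        ga_pct=ga,
        k=k,
    )


def population_summary(
    table: pd.DataFrame,
    variety: str,
    generation: str,
    traits: list[str] | None = None,
    treatments: list[str] | None = None,
    alpha: float = 0.05,
    k: float = DEFAULT_K,
) -> pd.DataFrame:
    """Per-(treatment, trait) summary: mean +/- SE, genetic parameters, letters.

    The genetic parameters come from the line-within-treatment ANOVA of each
    cell.  The letter display compares *treatment* means within each trait by
    Duncan's multiple range test, using per-line means as the replicate unit
    (so n per group equals the number of lines) — resolving the tables'
    ambiguous "n = 30" in favour of lines.
    """
    sub = table[(table["variety"] == variety) & (table["generation"] == generation)]
    if sub.empty:
        raise ValueError(f"no rows for ({variety!r}, {generation!r})")
    if traits is None:
        traits = list(dict.fromkeys(sub["trait"]))
    if treatments is None:
        treatments = list(dict.fromkeys(sub["treatment"]))
    rows = []
    for trait in traits:
        tsub = sub[sub["trait"] == trait]
        line_means = tsub.groupby(["treatment", "line"])["value"].mean()
        group_means, group_n = {}, {}
        for lab in treatments:
            lm = line_means.loc[lab]
            group_means[lab] = float(lm.mean())
            group_n[lab] = len(lm)
        ns = set(group_n.values())
        if len(ns) > 1:
            raise ValueError(
                f"trait {trait!r}: unequal line counts across treatments {group_n}"
            )
        n_lines = ns.pop()
        # pooled within-treatment variance of line means -> DMRT error term
        sse = 0.0
        for lab in treatments:
            lm = line_means.loc[lab]
            sse += float(((lm - lm.mean()) ** 2).sum())
        df_e = len(treatments) * (n_lines - 1)
        mse_lines = sse / df_e if df_e > 0 else 0.0
        if len(treatments) > 1 and df_e > 0:
            letters = dmrt_letters(
                group_means, r=n_lines, mse=mse_lines, df_e=df_e, alpha=alpha
            ).letters
        else:
            letters = {lab: "a" for lab in treatments}
        for lab in treatments:
            an = anova_lines(table, variety, generation, lab, trait)
            lm = line_means.loc[lab]
            se = float(lm.std(ddof=1) / math.sqrt(len(lm)))
            gp = genetic_parameters(an, grand_mean=group_means[lab], k=k, se_mean=se)
            rows.append(
                {
                    "variety": variety,
                    "generation": generation,
                    "treatment": lab,
                    "trait": trait,
                    "mean": gp.mean,
                    "se": gp.se_mean,
                    "letters": letters[lab],
                    "sigma2_g": gp.sigma2_g,
                    "sigma2_p": gp.sigma2_p,
                    "gcv_pct": gp.gcv_pct,
                    "h2_pct": gp.h2_pct,
                    "ga_pct": gp.ga_pct,
                    "n_lines": n_lines,
                    "r": an.r,
                }
            )
    return pd.DataFrame(rows)
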