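"""CSV interchange and report rendering.

The canonical interchange format is one long-format CSV of replicate-level
observations with header
``variety,generation,treatment,line,replicate,trait,value`` (UTF-8, "."
decimal separator).  Readers validate on the way in and report offending
data line numbers (header = line 1).
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .pigments import PigmentReading
from .simulate import TRAIT_TABLE_COLUMNS

TRAIT_KEY = ("variety", "generation", "treatment", "line", "replicate", "trait")


def write_trait_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a long-format trait table (full float precision)."""
    table[list(TRAIT_TABLE_COLUMNS)].to_csv(path, index=False)


def read_trait_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format trait table.

    Raises on a missing column, a non-numeric or missing value, a
    non-integer replicate index, or a duplicated observation key — always
    naming the first offending data line.
    """
    path = Path(path)
    table = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TRAIT_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path.name}: missing columns {missing}")
    lineno = table.index + 2  # header is line 1

    empty = table["value"].str.strip() == ""
    if empty.any():
        raise ValueError(
            f"{path.name}: missing value at line {int(lineno[empty][0])}"
        )
    na_like = table["value"].str.upper().isin({"NA", "NAN", "NULL", "NONE"})
    if na_like.any():
        raise ValueError(
            f"{path.name}: value {table['value'][na_like].iloc[0]!r} at line "
            f"{int(lineno[na_like][0])} denotes a missing observation; "
            "trait tables must be complete"
        )
    values = pd.to_numeric(table["value"], errors="coerce")
    bad = values.isna()
    if bad.any():
        raise ValueError(
            f"{path.name}: malformed numeric value "
            f"{table['value'][bad].iloc[0]!r} at line {int(lineno[bad][0])}"
        )
    finite = values.astype(float)
    nonfinite = ~np.isfinite(finite)
    if nonfinite.any():
        raise ValueError(
            f"{path.name}: non-finite value at line {int(lineno[nonfinite][0])}"
        )
    reps = pd.to_numeric(table["replicate"], errors="coerce")
    if reps.isna().any() or (reps != reps.round()).any() or (reps < 1).any():
        first = int(lineno[reps.isna() | (reps != reps.round()) | (reps < 1)][0])
        raise ValueError(
            f"{path.name}: replicate index must be a positive integer (line {first})"
        )
    out = table.copy()
    out["replicate"] = reps.astype(int)
    out["value"] = finite
    dup = out.duplicated(subset=list(TRAIT_KEY), keep="first")
    if dup.any():
        raise ValueError(
            f"{path.name}: duplicated observation key at line {int(lineno[dup][0])}"
        )
    return out[list(TRAIT_TABLE_COLUMNS)]


def read_germination_csv(path: str | Path) -> pd.DataFrame:
    """Read a germination-count table (treatment, sown, germinated[, %])."""
    path = Path(path)
    germ = pd.read_csv(path)
    for col in ("treatment", "sown", "germinated"):
        if col not in germ.columns:
            raise ValueError(f"{path.name}: missing column {col!r}")
    bad = (germ["germinated"] < 0) | (germ["germinated"] > germ["sown"])
    if bad.any():
        raise ValueError(
            f"{path.name}: germinated outside [0, sown] for treatment "
            f"{germ['treatment'][bad].iloc[0]!r}"
        )
    germ["germination_pct"] = 100.0 * germ["germinated"] / germ["sown"]
    return germ


def read_pigment_csv(path: str | Path) -> list[PigmentReading]:
    """Read spectrophotometer readings (od645,od663,od480,od510,v,w[,d])."""
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            kwargs = {k: float(v) for k, v in row.items() if v != "" and k != "sample"}
            out.append(PigmentReading(**kwargs))
    return out


def format_mean_cell(mean: float, letters: str, se: float) -> str:
    """Render one summary-table cell: ``93.75^h ± 0.32`` style."""
    return f"{mean:.2f}^{letters or 'a'} ± {se:.2f}"


def render_summary(summary: pd.DataFrame) -> str:
    """Text table in the trial's per-trait block layout.

    One block per trait: a MEAN row of caret-lettered ``mean ± SE`` cells
    followed by GCV %, h2 % and GA % rows, one column per treatment.
    """
    treatments = list(dict.fromkeys(summary["treatment"]))
    traits = list(dict.fromkeys(summary["trait"]))
    rows: list[list[str]] = [["Trait", "Statistic", *treatments]]
    for trait in traits:
        sub = summary[summary["trait"] == trait].set_index("treatment")
        rows.append(
            [trait, "MEAN"]
            + [
                format_mean_cell(
                    sub.loc[t, "mean"], str(sub.loc[t, "letters"]), sub.loc[t, "se"]
                )
                for t in treatments
            ]
        )
        for key, label in (("gcv_pct", "GCV%"), ("h2_pct", "h2%"), ("ga_pct", "GA")):
            rows.append(
                ["", label] + [f"{sub.loc[t, key]:.2f}" for t in treatments]
            )
    widths = [max(len(r[c]) for r in rows) for c in range(len(rows[0]))]
    lines = [
        "  ".join(cell.ljust(w) for cell, w in zip(row, widths)).rstrip()
        for row in rows
    ]
    return "\n".join(lines) + "\n"
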