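"""Duncan's multiple range test with compact-letter-display assignment.

Duncan's procedure compares the m group means after sorting them in
descending order.  A span of p adjacent ordered means is declared
non-significant when its range does not exceed the least significant range

    LSR(p) = q*(p, df_e, alpha_p) * SE_mean,   alpha_p = 1 - (1-alpha)^(p-1)

where q* is the studentized-range quantile at Duncan's protected level and
SE_mean = sqrt(MSE / r).  Two means are judged non-significantly different
when some span containing both has range <= its LSR; the maximal such spans
become the letters of the compact display (the superscripts of the trial's
summary tables).

Critical values are computed from the studentized-range distribution rather
than the historical 1955 tables, so any error df is reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

from scipy import stats


@lru_cache(maxsize=4096)
def _duncan_q_raw(p: int, df_e: int, alpha: float) -> float:
    alpha_p = 1.0 - (1.0 - alpha) ** (p - 1)
    return float(stats.studentized_range.ppf(1.0 - alpha_p, p, df_e))


@lru_cache(maxsize=4096)
def _duncan_q(p: int, df_e: int, alpha: float) -> float:
    # at small df the raw protected quantile can dip slightly as the span
    # grows; a significant range must not shrink, so floor each value at the
    # previous span's (as the classical tables do)
    return max(_duncan_q_raw(s, df_e, alpha) for s in range(2, p + 1))


def duncan_lsr(p: int, df_e: int, alpha: float, se_mean: float) -> float:
    """Least significant range for a span of ``p`` ordered means.

    Non-decreasing in ``p``; for p=2 the protection level collapses to
    ``alpha`` and the test reduces to a two-mean range test.
    """
    if p < 2:
        raise ValueError("span p must be >= 2")
    if df_e < 1:
        raise ValueError("df_e must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if se_mean < 0:
        raise ValueError("se_mean must be >= 0")
    if se_mean == 0:
        return 0.0
    return _duncan_q(p, int(df_e), float(alpha)) * se_mean


@dataclass(frozen=True)
class DmrtResult:
    """Outcome of Duncan's test over a set of group means.

    ``order`` lists labels by descending mean ('a' always covers the largest
    mean); ``letters`` maps label -> letter string; ``nonsig`` is the
    symmetric letter-sharing relation as a set of label pairs; ``lsr`` maps
    span p -> least significant range.
    """

    order: tuple[str, ...]
    means: dict[str, float]
    letters: dict[str, str]
    nonsig: frozenset[tuple[str, str]]
    lsr: dict[int, float]
    alpha: float
    df_e: int
    se_mean: float

    def share_letter(self, a: str, b: str) -> bool:
        return a == b or tuple(sorted((a, b))) in self.nonsig


def _nonsig_spans(ordered: list[float], lsr: dict[int, float]) -> list[tuple[int, int]]:
    """Maximal non-significant spans [i, j] of the descending-ordered means.

    Duncan's stepwise rule: a span is non-significant when its range is at
    most LSR(span size) *or* it lies inside an already accepted span; only
    the maximal accepted spans are reported.
    """
    m = len(ordered)
    accepted: list[tuple[int, int]] = []
    for size in range(m, 1, -1):
        for i in range(0, m - size + 1):
            j = i + size - 1
            if any(a <= i and j <= b for a, b in accepted):
                continue  # shielded by a containing non-significant span
            if ordered[i] - ordered[j] <= lsr[size]:
                accepted.append((i, j))
    covered = set()
    for a, b in accepted:
        covered.update(range(a, b + 1))
    singles = [(i, i) for i in range(m) if i not in covered]
    return sorted(accepted + singles)


def _letters_from_spans(n: int, spans: list[tuple[int, int]]) -> list[str]:
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    labels = []
    for k, _ in enumerate(spans):
        labels.append(
            alphabet[k] if k < 26 else alphabet[k // 26 - 1] + alphabet[k % 26]
        )
    out = ["" for _ in range(n)]
    for lab, (a, b) in zip(labels, spans):
        for i in range(a, b + 1):
            out[i] += lab
    return out


def dmrt_letters(
    means: dict[str, float],
    r: int,
    mse: float,
    df_e: int,
    alpha: float = 0.05,
) -> DmrtResult:
    """Duncan's multiple range test over balanced group means.

    ``means`` maps group label -> mean of ``r`` observations; ``mse`` and
    ``df_e`` come from the surrounding ANOVA.  Ties in means are broken by
    label so the output is deterministic.  Groups share a letter iff the
    stepwise Duncan procedure declares them non-significantly different.
    """
    if not means:
        raise ValueError("need at least one group")
    if mse < 0:
        raise ValueError("MSE must be >= 0")
    if r < 1:
        raise ValueError("group size r must be >= 1")
    order = sorted(means, key=lambda lab: (-means[lab], lab))
    m = len(order)
    se_mean = math.sqrt(mse / r)
    if m == 1:
        return DmrtResult(
            order=tuple(order), means=dict(means), letters={order[0]: "a"},
            nonsig=frozenset(), lsr={}, alpha=alpha, df_e=df_e, se_mean=se_mean,
        )
    lsr = {p: duncan_lsr(p, df_e, alpha, se_mean) for p in range(2, m + 1)}
    ordered_vals = [means[lab] for lab in order]
    spans = _nonsig_spans(ordered_vals, lsr)
    letter_list = _letters_from_spans(m, spans)
    letters = dict(zip(order, letter_list))
    pairs = set()
    for a, b in spans:
        for i in range(a, b + 1):
            for j in range(i + 1, b + 1):
                pairs.add(tuple(sorted((order[i], order[j]))))
    return DmrtResult(
        order=tuple(order),
        means=dict(means),
        letters=letters,
        nonsig=frozenset(pairs),
        lsr=lsr,
        alpha=alpha,
        df_e=df_e,
        se_mean=se_mean,
    )
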