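"""Cohort-level statistics: Wilcoxon rank-sum comparisons, descriptive
summaries, and Likert questionnaire medians.

The rank-sum test is implemented from first principles.  Let W be the sum
of (mid)ranks of the first sample in the pooled ordering.  For tie-free
pooled samples with n1+n2 <= ``EXACT_LIMIT`` the null distribution of W is
computed exactly by counting, for every achievable rank sum s, the number
of n1-subsets of {1..N} summing to s (a subset-sum dynamic program over
C(N, n1) equally likely rank assignments).  Otherwise a normal
approximation is used with the standard tie-corrected variance

    Var(W) = n1 n2 / 12 * (N + 1 - sum(t^3 - t) / (N (N - 1)))

and a 0.5 continuity correction.  Two-sided p-values are
min(1, 2 * min(P(W <= w), P(W >= w))).
"""

from __future__ import annotations

from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.stats import norm, rankdata

ALPHA = 0.05
#: largest pooled size for which the exact null distribution is enumerated
EXACT_LIMIT = 12

LIKERT_SCALE = (1, 7)

#: Usability questionnaire items (short labels; responses on a 1-7
#: agreement scale from strongly disagree to strongly agree).
LIKERT_QUESTIONS = {
    "Q1": "overall ease of use",
    "Q2": "comfort using the tool",
    "Q3": "ease of learning the simulator",
    "Q4": "error reporting and recovery guidance",
    "Q5": "clarity of the information shown",
    "Q6": "ease of finding information",
    "Q7": "understandability of the information",
    "Q8": "effectiveness of the information for the simulation",
    "Q9": "clarity of the on-screen organization",
    "Q10": "adequacy of the screen-element ordering",
    "Q11": "completeness of monitoring parameters shown",
    "Q12": "friendliness of the interface",
    "Q13": "appeal of the interface",
    "Q14": "completeness of simulator functionality",
    "Q15": "overall satisfaction",
}

Alternative = Literal["two-sided", "less", "greater"]


class GroupComparison(BaseModel):
    statistic: float  # rank sum of the first sample
    p_value: float = Field(ge=0, le=1)
    alternative: Alternative
    method: Literal["exact", "normal-approx-with-tie-correction", "degenerate"]
    n1: int = Field(ge=1)
    n2: int = Field(ge=1)
    significant: bool

    @model_validator(mode="after")
    def _consistent(self) -> "GroupComparison":
        if self.significant != (self.p_value < ALPHA):
            raise ValueError("significant flag inconsistent with p-value")
        return self


def _exact_rank_sum_tails(n1: int, n2: int, w: float) -> tuple[float, float]:
    """(P(W <= w), P(W >= w)) under the exact tie-free null.

    counts[k][s] = number of k-subsets of ranks {1..N} with sum s.
    """
    N = n1 + n2
    max_sum = N * (N + 1) // 2
    counts = np.zeros((n1 + 1, max_sum + 1), dtype=np.int64)
    counts[0, 0] = 1
    for rank in range(1, N + 1):
        # iterate k downward so each rank is used at most once
        for k in range(min(rank, n1), 0, -1):
            counts[k, rank:] += counts[k - 1, : max_sum + 1 - rank]
    dist = counts[n1]
    total = dist.sum()
    sums = np.arange(max_sum + 1)
    p_le = dist[sums <= w].sum() / total
    p_ge = dist[sums >= w].sum() / total
    return float(p_le), float(p_ge)


def _approx_rank_sum_tails(
    w: float, n1: int, n2: int, pooled_ranks: np.ndarray
) -> tuple[float, float]:
    N = n1 + n2
    mean = n1 * (N + 1) / 2.0
    _, tie_counts = np.unique(pooled_ranks, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (N * (N - 1)))
    var = n1 * n2 / 12.0 * (N + 1 - tie_term)
    sd = np.sqrt(var)
    # continuity-corrected tails
    p_le = float(norm.cdf((w - mean + 0.5) / sd))
    p_ge = float(norm.sf((w - mean - 0.5) / sd))
    return min(p_le, 1.0), min(p_ge, 1.0)


def rank_sum_test(
    a: Sequence[float],
    b: Sequence[float],
    alternative: Alternative = "two-sided",
) -> GroupComparison:
    """Wilcoxon rank-sum test comparing samples ``a`` and ``b``.

    ``alternative="greater"`` tests whether ``a`` tends to exceed ``b``.
    A constant pooled sample carries no ordering evidence: p = 1, flagged
    with method ``"degenerate"``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # midranks for ties
    w = float(ranks[:n1].sum())

    if np.all(pooled == pooled[0]):
        return GroupComparison(
            statistic=w, p_value=1.0, alternative=alternative,
            method="degenerate", n1=n1, n2=n2, significant=False,
        )

    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and n1 + n2 <= EXACT_LIMIT:
        p_le, p_ge = _exact_rank_sum_tails(n1, n2, w)
        method = "exact"
    else:
        p_le, p_ge = _approx_rank_sum_tails(w, n1, n2, ranks)
        method = "normal-approx-with-tie-correction"

    if alternative == "two-sided":
        p = min(1.0, 2.0 * min(p_le, p_ge))
    elif alternative == "greater":
        p = p_ge
    else:
        p = p_le
    return GroupComparison(
        statistic=w, p_value=float(p), alternative=alternative,
        method=method, n1=n1, n2=n2, significant=bool(p < ALPHA),
    )


def describe(sample: Sequence[float]) -> dict[str, float]:
    """Mean, sample SD (n-1), median and linearly interpolated quartiles."""
    x = np.asarray(sample, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation
    sd = 0.0 if x.size < 2 else float(np.std(x, ddof=1))
    return {
        "mean": float(x.mean()),
        "sd": sd,
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "n": int(x.size),
    }


class LikertSummary(BaseModel):
    per_question: dict[str, dict[str, float]]  # question -> group -> median
    overall: dict[str, float]                  # question -> pooled median
    groups: list[str]


def summarize_likert(
    responses: pd.DataFrame,
    group_col: str = "group",
) -> LikertSummary:
    """Per-question, per-group and overall medians of 1-7 Likert ratings.

    ``responses`` has one row per respondent: a ``group`` column plus one
    column per question id (Q1..Q15).  Ratings must be integers in [1, 7].
    """
    question_cols = [c for c in responses.columns if c.startswith("Q")]
    unknown = set(question_cols) - set(LIKERT_QUESTIONS)
    if unknown:
        raise ValueError(f"unknown question ids: {sorted(unknown)}")
    if not question_cols:
        raise ValueError("no question columns (Q1..Q15) found")
    if group_col not in responses.columns:
        raise ValueError(f"missing group column {group_col!r}")

    ratings = responses[question_cols]
    lo, hi = LIKERT_SCALE
    bad = ratings.apply(
        lambda col: ~col.apply(lambda v: float(v).is_integer() and lo <= v <= hi)
    )
    if bad.to_numpy().any():
        rows, cols = np.nonzero(bad.to_numpy())
        first = (responses.index[rows[0]], question_cols[cols[0]])
        raise ValueError(
            f"rating outside the {lo}-{hi} scale (first at row {first[0]}, "
            f"{first[1]})"
        )

    groups = sorted(responses[group_col].unique())
    per_question: dict[str, dict[str, float]] = {}
    overall: dict[str, float] = {}
    for q in question_cols:
        overall[q] = float(responses[q].median())
        per_question[q] = {
            g: float(responses.loc[responses[group_col] == g, q].median())
            for g in groups
        }
    return LikertSummary(
        per_question=per_question, overall=overall, groups=[str(g) for g in groups]
    )
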