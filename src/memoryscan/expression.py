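"""Classification of TNF-α-responsive and transcriptional-memory genes.

The experimental design has five conditions: no induction (``naive_0h``),
an acute first induction (``first_12h``), sustained stimulation
(``sustained_12d``), a 10-day recovery without stimulus (``recovery_10d``)
and a second acute induction after recovery (``second_12h``).

A gene is *responsive* when its first-induction fold change exceeds 2 with
p < 0.01, and a responsive gene carries *transcriptional memory* when the
second induction is at least 1.3-fold stronger than the first and reaches an
FPKM above 5. A pseudocount of 1 FPKM is applied to every ratio and log so
all statistics are defined for silent genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import (
    DEFAULT_ALPHA,
    DEFAULT_FC_MIN,
    DEFAULT_FPKM_MIN,
    DEFAULT_MEMORY_RATIO,
)

PSEUDOCOUNT = 1.0

CONDITIONS = ("naive_0h", "first_12h", "sustained_12d", "recovery_10d", "second_12h")


class ExpressionMatrix:
    """Gene × condition × replicate FPKM table.

    Wraps a DataFrame whose columns are a 2-level MultiIndex
    ``(condition, replicate)`` and whose index is the gene id.
    """

    def __init__(self, data: pd.DataFrame):
        if not isinstance(data.columns, pd.MultiIndex) or data.columns.nlevels != 2:
            raise ValueError("expected MultiIndex columns (condition, replicate)")
        if (data.to_numpy() < 0).any():
            raise ValueError("FPKM values must be non-negative")
        for cond in data.columns.get_level_values(0).unique():
            if data[cond].shape[1] < 1:
                raise ValueError(f"condition {cond!r} has no replicates")
        self.data = data.sort_index()

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.data.columns.get_level_values(0)))

    def require(self, *conditions: str) -> None:
        missing = [c for c in conditions if c not in self.conditions]
        if missing:
            raise ValueError(f"missing condition(s): {', '.join(missing)}")

    def condition_values(self, condition: str) -> pd.DataFrame:
        self.require(condition)
        return self.data[condition]

    def condition_mean(self, condition: str) -> pd.Series:
        return self.condition_values(condition).mean(axis=1)

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        cols = []
        for c in df.columns:
            if ":" not in c:
                raise ValueError(
                    f"expression column {c!r} is not in 'condition:replicate' form"
                )
            cond, rep = c.split(":", 1)
            cols.append((cond, rep))
        df.columns = pd.MultiIndex.from_tuples(cols, names=["condition", "replicate"])
        return cls(df)

    def to_tsv(self, path) -> None:
        flat = self.data.copy()
        flat.columns = [f"{c}:{r}" for c, r in flat.columns]
        flat.index.name = "gene"
        flat.to_csv(path, sep="\t")


def fold_change(numerator_mean: pd.Series, denominator_mean: pd.Series) -> pd.Series:
    """Pseudocounted ratio of condition means: (a + 1) / (b + 1)."""
    return (numerator_mean + PSEUDOCOUNT) / (denominator_mean + PSEUDOCOUNT)


def welch_log_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Welch t-test on log2(FPKM + 1) across replicates."""
    la, lb = np.log2(np.asarray(a) + PSEUDOCOUNT), np.log2(np.asarray(b) + PSEUDOCOUNT)
    if len(la) < 2 or len(lb) < 2:
        return float("nan")
    if np.allclose(la, la[0]) and np.allclose(lb, lb[0]):
        return 1.0 if np.isclose(la[0], lb[0]) else 0.0
    return float(stats.ttest_ind(la, lb, equal_var=False).pvalue)


def call_responsive(
    expr: ExpressionMatrix,
    fc_min: float = DEFAULT_FC_MIN,
    alpha: float = DEFAULT_ALPHA,
    p_values: Mapping[str, float] | None = None,
    test: Callable[[np.ndarray, np.ndarray], float] = welch_log_p,
) -> pd.DataFrame:
    """Call TNF-α-responsive genes from the first acute induction.

    Responsive = fold change (first_12h vs naive_0h, pseudocounted means)
    strictly greater than ``fc_min`` AND test p-value below ``alpha``.
    Externally computed p-values (e.g. from a count-based DE engine) can be
    injected via ``p_values`` keyed by gene; the built-in default is a
    two-sided Welch t on log2(FPKM + 1).
    """
    expr.require("naive_0h", "first_12h")
    naive = expr.condition_values("naive_0h")
    first = expr.condition_values("first_12h")
    fold = fold_change(first.mean(axis=1), naive.mean(axis=1))
    if p_values is not None:
        pv = pd.Series({g: p_values.get(g, float("nan")) for g in expr.genes})
    else:
        pv = pd.Series(
            [test(first.loc[g].to_numpy(), naive.loc[g].to_numpy()) for g in expr.genes],
            index=expr.genes,
        )
    out = pd.DataFrame(
        {
            "fold_12h_vs_0h": fold,
            "p_value": pv,
            "responsive": (fold > fc_min) & (pv < alpha),
        }
    )
    out.index.name = "gene"
    return out


def baseline_elevation(expr: ExpressionMatrix) -> pd.Series:
    """Per-gene recovery_10d vs naive_0h ratio of means (pseudocounted).

    Reported, not thresholded: elevated baselines after stimulus withdrawal
    are a hallmark of the strongest memory genes but not a defining criterion.
    """
    expr.require("naive_0h", "recovery_10d")
    return fold_change(
        expr.condition_mean("recovery_10d"), expr.condition_mean("naive_0h")
    ).rename("baseline_fold_recovery_vs_naive")


def call_memory(
    expr: ExpressionMatrix,
    responsive: pd.DataFrame,
    ratio_min: float = DEFAULT_MEMORY_RATIO,
    fpkm_min: float = DEFAULT_FPKM_MIN,
) -> pd.DataFrame:
    """Call transcriptional-memory genes among the responsive set.

    Memory = responsive AND second/first induction ratio (pseudocounted
    means) at least ``ratio_min`` (inclusive) AND mean FPKM in the second
    induction strictly above ``fpkm_min``. One row per gene with all
    classifier statistics; the memory flag implies the responsive flag.
    """
    expr.require("first_12h", "second_12h")
    unknown = responsive.index.difference(expr.genes)
    if len(unknown) > 0:
        raise ValueError(f"responsive set references unknown genes: {list(unknown)}")
    first_mean = expr.condition_mean("first_12h")
    second_mean = expr.condition_mean("second_12h")
    ratio = fold_change(second_mean, first_mean)
    out = responsive.copy()
    out["fold_second_vs_first"] = ratio
    out["fpkm_second"] = second_mean
    try:
        out["baseline_fold_recovery_vs_naive"] = baseline_elevation(expr)
    except ValueError:
        out["baseline_fold_recovery_vs_naive"] = float("nan")
    out["memory"] = (
        out["responsive"] & (ratio >= ratio_min) & (second_mean > fpkm_min)
    )
    return out


def memory_genes(calls: pd.DataFrame) -> list[str]:
    """Gene ids flagged as memory genes, sorted."""
    return sorted(calls.index[calls["memory"]])


def transcriptome_correlation(
    expr: ExpressionMatrix, cond_a: str, cond_b: str
) -> float:
    """Pearson r of log2(mean FPKM + 1) between two conditions across genes.

    Near-identical transcriptomes (r ≈ 1) outside the primed memory genes are
    the expected signature of memory consolidation without a global shift.
    """
    expr.require(cond_a, cond_b)
    if len(expr.genes) < 3:
        raise ValueError("need at least 3 genes for a correlation")
    a = np.log2(expr.condition_mean(cond_a).to_numpy() + PSEUDOCOUNT)
    b = np.log2(expr.condition_mean(cond_b).to_numpy() + PSEUDOCOUNT)
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        raise ValueError("zero variance in a condition; correlation undefined")
    return float(stats.pearsonr(a, b).statistic)


@dataclass(frozen=True)
class GroupTestResult:
    group: str
    n: int
    t_statistic: float
    p_value: float
    mean_log2_change: float

    @property
    def direction(self) -> str:
        if self.mean_log2_change > 0:
            return "up"
        if self.mean_log2_change < 0:
            return "down"
        return "none"


def erna_group_test(
    erna_first: Mapping[str, float],
    erna_second: Mapping[str, float],
    groups: Mapping[str, Sequence[str]],
) -> list[GroupTestResult]:
    """Paired two-tailed t-test of eRNA change per peak group.

    For each group of peaks, tests log2(RPKM + 1) differences
    (second − first induction) against zero. Used to ask whether highly
    demethylated peaks gain more enhancer transcription on re-induction.
    """
    results = []
    for name, peak_ids in groups.items():
        if len(peak_ids) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 peaks")
        diffs = np.array(
            [
                math.log2(erna_second[p] + PSEUDOCOUNT)
                - math.log2(erna_first[p] + PSEUDOCOUNT)
                for p in peak_ids
            ]
        )
        if np.allclose(diffs, 0.0):
            t, p = 0.0, 1.0
        else:
            res = stats.ttest_rel(
                [math.log2(erna_second[p] + PSEUDOCOUNT) for p in peak_ids],
                [math.log2(erna_first[p] + PSEUDOCOUNT) for p in peak_ids],
            )
            t, p = float(res.statistic), float(res.pvalue)
        results.append(
            GroupTestResult(
                group=name,
                n=len(peak_ids),
                t_statistic=t,
                p_value=p,
                mean_log2_change=float(diffs.mean()),
            )
        )
    return results


def dose_fold_ratio(reference_dose: float = 50.0, low_dose: float = 0.4) -> float:
    """Fold reduction between a reference and a low stimulus dose (ng/mL).

    Memory-consolidated cells respond to a far lower cytokine dose than naïve
    cells; with the default doses of 50 and 0.4 ng/mL the sensitization
    factor is 125-fold.
    """
    if reference_dose <= 0 or low_dose <= 0:
        raise ValueError("doses must be positive")
    return reference_dose / low_dose
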