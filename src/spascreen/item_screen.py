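"""Per-item case--control screening: 2x2 tests and demographic comparisons.

Each questionnaire item is cross-tabulated against case status, once per
control group, and tested with Pearson's chi-square or Fisher's exact test.
The test is chosen by Cochran's rule: the exact test whenever any expected
cell count falls below 5.  An item is "discriminating" when it differs
significantly from the cases in at least one control comparison.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortDataset

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "ItemComparison",
    "ItemScreenReport",
    "make_table",
    "pearson_chi2",
    "fisher_exact",
    "choose_test",
    "two_sample_t",
    "two_sample_t_raw",
    "screen_items",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts a = group-A/yes, b = group-A/no, c = group-B/yes, d = group-B/no."""

    a: int
    b: int
    c: int
    d: int
    label_a: str = "case"
    label_b: str = "control"

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def expected(self) -> np.ndarray:
        """Expected counts under independence, same layout as (a, b, c, d)."""
        r1, r2 = self.a + self.b, self.c + self.d
        c1, c2 = self.a + self.c, self.b + self.d
        n = self.n
        if n == 0:
            raise ValueError("empty table")
        return np.array([r1 * c1, r1 * c2, r2 * c1, r2 * c2], dtype=float) / n


@dataclass(frozen=True)
class TestResult:
    method: str  # pearson_chi2 | fisher_exact | student_t | degenerate_constant
    p_value: float
    statistic: float | None = None
    df: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 + 1e-12):
            raise ValueError("p-value outside [0, 1]")


def make_table(
    dataset: CohortDataset, item: str, group_a: str, group_b: str
) -> ContingencyTable2x2:
    present = dataset.groups
    for g in (group_a, group_b):
        if g not in present:
            raise ValueError(f"group {g!r} not present in cohort")
    xa = dataset.item_column(item, group_a)
    xb = dataset.item_column(item, group_b)
    return ContingencyTable2x2(
        a=int(xa.sum()),
        b=int(len(xa) - xa.sum()),
        c=int(xb.sum()),
        d=int(len(xb) - xb.sum()),
        label_a=group_a,
        label_b=group_b,
    )


def pearson_chi2(table: ContingencyTable2x2) -> TestResult:
    """Uncorrected Pearson chi-square on a 2x2 table:
    ``N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))`` with 1 df."""
    a, b, c, d = table.a, table.b, table.c, table.d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if min(margins) == 0:
        raise ValueError(
            "zero marginal: chi-square undefined, use fisher_exact"
        )
    n = table.n
    stat = n * (a * d - b * c) ** 2 / math.prod(margins)
    return TestResult(
        method="pearson_chi2",
        statistic=float(stat),
        df=1,
        p_value=float(stats.chi2.sf(stat, 1)),
    )


def fisher_exact(table: ContingencyTable2x2) -> TestResult:
    """Two-sided Fisher's exact test (sum of hypergeometric probabilities not
    exceeding that of the observed table)."""
    _, p = stats.fisher_exact(
        [[table.a, table.b], [table.c, table.d]], alternative="two-sided"
    )
    return TestResult(method="fisher_exact", p_value=float(min(p, 1.0)))


def choose_test(table: ContingencyTable2x2) -> str:
    """Cochran's rule: exact test if any expected cell count is below 5."""
    try:
        expected = table.expected()
    except ValueError:
        return "fisher_exact"
    return "fisher_exact" if (expected < 5).any() else "pearson_chi2"


def two_sample_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> TestResult:
    """Two-sided pooled-variance Student t-test from summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least 2 observations")
    if sd1 <= 0 and sd2 <= 0 and mean1 == mean2:
        return TestResult(
            method="student_t", statistic=0.0, df=n1 + n2 - 2, p_value=1.0
        )
    t, p = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=True
    )
    return TestResult(
        method="student_t", statistic=float(t), df=n1 + n2 - 2, p_value=float(p)
    )


def two_sample_t_raw(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Same test from raw data; agrees with the summary form by construction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return two_sample_t(
        float(x.mean()), float(x.std(ddof=1)), len(x),
        float(y.mean()), float(y.std(ddof=1)), len(y),
    )


def _run_test(table: ContingencyTable2x2) -> TestResult:
    # Constant item in both groups with the same value: nothing to test.
    if (table.a + table.c == 0) or (table.b + table.d == 0):
        return TestResult(method="degenerate_constant", p_value=1.0)
    method = choose_test(table)
    return fisher_exact(table) if method == "fisher_exact" else pearson_chi2(table)


@dataclass(frozen=True)
class ItemComparison:
    item_id: str
    text_key: str
    control_group: str
    table: ContingencyTable2x2
    result: TestResult
    significant: bool
    significant_bonferroni: bool


@dataclass(frozen=True)
class ItemScreenReport:
    comparisons: tuple[ItemComparison, ...]
    demographics: dict = field(compare=False)
    alpha: float = 0.05

    @property
    def n_items(self) -> int:
        return len({c.item_id for c in self.comparisons})

    @property
    def discriminating_items(self) -> tuple[str, ...]:
        """Items significant versus at least one control group, in item order."""
        sig = [c.item_id for c in self.comparisons if c.significant]
        out: list[str] = []
        for c in self.comparisons:
            if c.item_id in sig and c.item_id not in out:
                out.append(c.item_id)
        return tuple(out)

    @property
    def n_discriminating(self) -> int:
        return len(self.discriminating_items)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.comparisons:
            rows.append(
                {
                    "item": c.item_id,
                    "text_key": c.text_key,
                    "control_group": c.control_group,
                    "a": c.table.a,
                    "b": c.table.b,
                    "c": c.table.c,
                    "d": c.table.d,
                    "method": c.result.method,
                    "statistic": c.result.statistic,
                    "df": c.result.df,
                    "p": c.result.p_value,
                    "significant": c.significant,
                    "significant_bonferroni": c.significant_bonferroni,
                }
            )
        return pd.DataFrame(rows)

    def write(self, tsv_path: str | Path, json_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(tsv_path, sep="\t", index=False)
        if json_path is not None:
            summary = {
                "n_items": self.n_items,
                "n_discriminating": self.n_discriminating,
                "discriminating_items": list(self.discriminating_items),
                "alpha": self.alpha,
            }
            Path(json_path).write_text(json.dumps(summary, indent=2))


def screen_items(dataset: CohortDataset, alpha: float = 0.05) -> ItemScreenReport:
    """Test every item against each control group present in the cohort.

    Bonferroni-flagged significance (over items x comparisons) is reported as
    supplementary information only; the discriminating flag uses plain alpha.
    """
    controls = [g for g in dataset.groups if g != "case"]
    if "case" not in dataset.groups or not controls:
        raise ValueError("cohort must contain cases and at least one control group")

    n_tests = len(dataset.items) * len(controls)
    comparisons: list[ItemComparison] = []
    for item in dataset.items:
        for ctrl in controls:
            table = make_table(dataset, item.item_id, "case", ctrl)
            result = _run_test(table)
            comparisons.append(
                ItemComparison(
                    item_id=item.item_id,
                    text_key=item.text_key,
                    control_group=ctrl,
                    table=table,
                    result=result,
                    significant=result.p_value < alpha,
                    significant_bonferroni=result.p_value < alpha / n_tests,
                )
            )

    demographics: dict[str, TestResult | None] = {}
    case_ages = dataset.ages("case")
    case_onsets = dataset.onsets("case")
    for ctrl in controls:
        demographics[f"age_vs_{ctrl}"] = two_sample_t_raw(
            case_ages, dataset.ages(ctrl)
        )
        onsets = dataset.onsets(ctrl)
        if len(case_onsets) >= 2 and len(onsets) >= 2:
            demographics[f"onset_vs_{ctrl}"] = two_sample_t_raw(case_onsets, onsets)
        else:
            demographics[f"onset_vs_{ctrl}"] = None

    return ItemScreenReport(
        comparisons=tuple(comparisons), demographics=demographics, alpha=alpha
    )
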