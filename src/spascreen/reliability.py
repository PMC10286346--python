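"""Reliability and validity of the extracted components, item reduction and
the referral cutoff.

Each component found by the factor stage becomes a candidate sub-scale.  Its
internal consistency is Cronbach's alpha; convergent and discriminative
validity are multitrait scaling-success rates computed from corrected
item--scale correlations (an item is correlated with its own scale after
removing itself from the total, and with every other scale's total).  A
component survives only if alpha, convergent validity and discriminative
validity all reach the 0.70 floor.  The surviving components are merged into
one screening scale whose referral cutoff is the floor of (global alpha x
maximum score).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CohortDataset
from .factor import ComponentAssignment

__all__ = [
    "ReliabilityRow",
    "ReliabilityReport",
    "ItemScaleCorrelations",
    "MergedScale",
    "alpha_from_matrix",
    "cronbach_alpha",
    "standardized_alpha",
    "item_scale_correlations",
    "scaling_success",
    "component_reliability_report",
    "retention_filter",
    "referral_cutoff",
    "merge_scale",
    "merge_published_scale",
]

RELIABILITY_FLOOR = 0.70
CONVERGENCE_FLOOR = 0.40


def alpha_from_matrix(x: np.ndarray) -> float:
    """Cronbach's alpha of an n x p score matrix.

    alpha = (p / (p - 1)) * (1 - sum of item variances / variance of the
    total score), variances with the n-1 denominator.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("Cronbach's alpha needs at least 2 items")
    if x.shape[0] < 2:
        raise ValueError("Cronbach's alpha needs at least 2 subjects")
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total-score variance is zero; alpha undefined")
    p = x.shape[1]
    return float(p / (p - 1) * (1.0 - x.var(axis=0, ddof=1).sum() / total_var))


def cronbach_alpha(dataset: CohortDataset, items: Sequence[str]) -> float:
    """Cronbach's alpha of a multi-item scale over all subjects in the cohort."""
    if len(items) < 2:
        raise ValueError("Cronbach's alpha needs at least 2 items")
    return alpha_from_matrix(
        np.column_stack([dataset.item_column(it) for it in items])
    )


def standardized_alpha(dataset: CohortDataset, items: Sequence[str]) -> float:
    """Spearman--Brown standardized alpha: p * rbar / (1 + (p - 1) * rbar)
    with rbar the mean off-diagonal inter-item correlation."""
    if len(items) < 2:
        raise ValueError("standardized alpha needs at least 2 items")
    x = np.column_stack([dataset.item_column(it) for it in items])
    r = np.corrcoef(x, rowvar=False)
    p = x.shape[1]
    off = ~np.eye(p, dtype=bool)
    rbar = float(r[off].mean())
    return p * rbar / (1.0 + (p - 1) * rbar)


@dataclass(frozen=True)
class ItemScaleCorrelations:
    """Item x component correlation matrix.

    The entry for an item against its *own* component is corrected for
    overlap (the item is removed from the scale total before correlating).
    ``degenerate`` lists (item, component) pairs where a zero-variance scale
    forced the correlation to 0.
    """

    matrix: pd.DataFrame  # rows: item_id, columns: component index (int)
    assignment: ComponentAssignment
    degenerate: tuple = ()

    def own(self, item: str) -> float:
        comp = self.assignment.assignments[item][0]
        return float(self.matrix.loc[item, comp])

    def cross(self, item: str, component: int) -> float:
        return float(self.matrix.loc[item, component])


def _safe_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    if x.std() == 0 or y.std() == 0:
        return 0.0, True
    return float(np.corrcoef(x, y)[0, 1]), False


def item_scale_correlations(
    dataset: CohortDataset, assignment: ComponentAssignment
) -> ItemScaleCorrelations:
    """Correlate every assigned item with every component's scale score,
    correcting own-scale correlations for overlap."""
    if not assignment.assignments:
        raise ValueError("empty assignment")
    comps = [
        c for c in assignment.components() if assignment.component_items(c)
    ]
    totals = {
        c: np.column_stack(
            [dataset.item_column(it) for it in assignment.component_items(c)]
        ).sum(axis=1)
        for c in comps
    }
    rows = {}
    degenerate = []
    for item, (own_comp, _) in assignment.assignments.items():
        x = dataset.item_column(item)
        row = {}
        for c in comps:
            total = totals[c]
            if c == own_comp:
                total = total - x  # corrected for overlap
            r, bad = _safe_corr(x, total)
            if bad:
                degenerate.append((item, c))
            row[c] = r
        rows[item] = row
    matrix = pd.DataFrame.from_dict(rows, orient="index")[comps]
    return ItemScaleCorrelations(
        matrix=matrix, assignment=assignment, degenerate=tuple(degenerate)
    )


def scaling_success(
    correlations: ItemScaleCorrelations,
    convergence_floor: float = CONVERGENCE_FLOOR,
) -> dict[int, tuple[float, float | None]]:
    """Multitrait scaling-success rates per component.

    convergent: fraction of the component's items whose corrected own-scale
    correlation reaches ``convergence_floor``.  discriminative: fraction of
    (item, other scale) checks where the corrected own-scale correlation
    strictly exceeds the cross-scale one; ``None`` when there is no other
    component to compare against.
    """
    assignment = correlations.assignment
    comps = [c for c in assignment.components() if assignment.component_items(c)]
    out: dict[int, tuple[float, float | None]] = {}
    for c in comps:
        items = assignment.component_items(c)
        conv_hits = sum(
            1 for it in items if correlations.own(it) >= convergence_floor
        )
        convergent = conv_hits / len(items)
        others = [o for o in comps if o != c]
        if not others:
            out[c] = (convergent, None)
            continue
        checks = 0
        wins = 0
        for it in items:
            own_r = correlations.own(it)
            for o in others:
                checks += 1
                if own_r > correlations.cross(it, o):
                    wins += 1
        out[c] = (convergent, wins / checks)
    return out


@dataclass(frozen=True)
class ReliabilityRow:
    component: int
    n_items: int
    items: tuple[str, ...]
    score_mean: float | None
    score_sd: float | None
    alpha: float | None
    convergent: float | None
    discriminative: float | None
    retained: bool = False


@dataclass(frozen=True)
class ReliabilityReport:
    rows: tuple[ReliabilityRow, ...]
    floor: float = RELIABILITY_FLOOR
    convergence_floor: float = CONVERGENCE_FLOOR

    @property
    def retained_components(self) -> tuple[int, ...]:
        return tuple(r.component for r in self.rows if r.retained)

    def row(self, component: int) -> ReliabilityRow:
        for r in self.rows:
            if r.component == component:
                return r
        raise KeyError(component)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "component": f"C{r.component}",
                    "n_items": r.n_items,
                    "mean": r.score_mean,
                    "sd": r.score_sd,
                    "alpha": r.alpha,
                    "convergent_validity": r.convergent,
                    "discriminative_validity": r.discriminative,
                    "retained": r.retained,
                }
                for r in self.rows
            ]
        )

    def write(self, tsv_path: str | Path) -> None:
        self.to_frame().to_csv(tsv_path, sep="\t", index=False)


def _meets(value: float | None, floor: float) -> bool:
    # criteria that are structurally undefined (single component, 1-item
    # scale) cannot veto retention on their own; alpha None always vetoes
    return value is None or value >= floor


def retention_filter(
    report: ReliabilityReport, floor: float = RELIABILITY_FLOOR
) -> tuple[int, ...]:
    """Components retained iff alpha, convergent and discriminative validity
    all reach the floor (boundary inclusive); failing any criterion excludes."""
    retained = []
    for r in report.rows:
        if r.alpha is None or r.alpha < floor:
            continue
        if not _meets(r.convergent, floor):
            continue
        if not _meets(r.discriminative, floor):
            continue
        retained.append(r.component)
    return tuple(retained)


def component_reliability_report(
    dataset: CohortDataset,
    assignment: ComponentAssignment,
    floor: float = RELIABILITY_FLOOR,
    convergence_floor: float = CONVERGENCE_FLOOR,
) -> ReliabilityReport:
    """Per-component reliability/validity table (alpha, scaling success,
    retention flag) computed over all subjects in the cohort."""
    correlations = item_scale_correlations(dataset, assignment)
    success = scaling_success(correlations, convergence_floor)
    rows: list[ReliabilityRow] = []
    comps = [c for c in assignment.components() if assignment.component_items(c)]
    for c in comps:
        items = assignment.component_items(c)
        score = np.column_stack(
            [dataset.item_column(it) for it in items]
        ).sum(axis=1)
        try:
            alpha = cronbach_alpha(dataset, items)
        except ValueError:
            alpha = None
        convergent, discriminative = success[c]
        rows.append(
            ReliabilityRow(
                component=c,
                n_items=len(items),
                items=items,
                score_mean=float(score.mean()),
                score_sd=float(score.std(ddof=1)),
                alpha=alpha,
                convergent=convergent,
                discriminative=discriminative,
            )
        )
    provisional = ReliabilityReport(
        rows=tuple(rows), floor=floor, convergence_floor=convergence_floor
    )
    retained = set(retention_filter(provisional, floor))
    rows = [
        ReliabilityRow(
            component=r.component,
            n_items=r.n_items,
            items=r.items,
            score_mean=r.score_mean,
            score_sd=r.score_sd,
            alpha=r.alpha,
            convergent=r.convergent,
            discriminative=r.discriminative,
            retained=r.component in retained,
        )
        for r in rows
    ]
    return ReliabilityReport(
        rows=tuple(rows), floor=floor, convergence_floor=convergence_floor
    )


@dataclass(frozen=True)
class MergedScale:
    """The reduced screening instrument: retained items, global alpha, and
    the referral cutoff (floor of global alpha x maximum score)."""

    items: tuple[str, ...]
    global_alpha: float
    max_score: int
    cutoff: int
    rounding_rule: str = "floor"
    standardized_alpha: float | None = None

    def to_json_dict(self) -> dict:
        return {
            "items": list(self.items),
            "global_alpha": self.global_alpha,
            "standardized_alpha": self.standardized_alpha,
            "max_score": self.max_score,
            "cutoff": self.cutoff,
            "rounding_rule": self.rounding_rule,
        }

    def write(self, json_path: str | Path) -> None:
        Path(json_path).write_text(json.dumps(self.to_json_dict(), indent=2))


def referral_cutoff(
    global_alpha: float, max_score: int, rule: str = "floor"
) -> int:
    """Referral threshold: the reliability fraction of the maximum score,
    rounded down (``"ceil"`` available as the documented alternative)."""
    if not (0.0 <= global_alpha <= 1.0):
        raise ValueError("global_alpha must lie in [0, 1]")
    if max_score < 1:
        raise ValueError("max_score must be positive")
    raw = global_alpha * max_score
    if rule == "floor":
        return int(math.floor(raw))
    if rule == "ceil":
        return int(math.ceil(raw))
    raise ValueError(f"unknown rounding rule {rule!r}")


def merge_scale(
    dataset: CohortDataset,
    retained: Sequence[int],
    assignment: ComponentAssignment,
    rounding_rule: str = "floor",
) -> MergedScale:
    """Merge the retained components into one scale and derive its cutoff."""
    if not retained:
        raise ValueError("no retained components to merge")
    items: list[str] = []
    for c in retained:
        items.extend(assignment.component_items(c))
    if len(items) < 2:
        raise ValueError("merged scale needs at least 2 items")
    alpha = cronbach_alpha(dataset, items)
    return MergedScale(
        items=tuple(items),
        global_alpha=alpha,
        max_score=len(items),
        cutoff=referral_cutoff(alpha, len(items), rounding_rule),
        rounding_rule=rounding_rule,
        standardized_alpha=standardized_alpha(dataset, items),
    )


def merge_published_scale(
    component_items: Sequence[Sequence[str]],
    global_alpha: float,
    rounding_rule: str = "floor",
) -> MergedScale:
    """Build a merged scale from already-published component item lists and a
    reported global reliability (no subject data involved)."""
    items: list[str] = []
    for comp in component_items:
        items.extend(comp)
    return MergedScale(
        items=tuple(items),
        global_alpha=global_alpha,
        max_score=len(items),
        cutoff=referral_cutoff(global_alpha, len(items), rounding_rule),
        rounding_rule=rounding_rule,
    )
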