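"""ROC-based screening performance of the merged referral scale.

Subjects are scored by counting positive responses on the retained items;
the referral rule "score >= cutoff" is swept over every integer cutoff to
trace the ROC curve.  The trapezoidal AUC over that sweep equals the
Mann--Whitney concordance probability (ties counted one half), which is the
cross-check used in the tests.  Confidence intervals use the Hanley--McNeil
standard error by default, with DeLong available behind a flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortDataset
from .reliability import MergedScale

__all__ = [
    "ReferralResult",
    "RocPoint",
    "RocAnalysis",
    "score_subjects",
    "roc_curve",
    "mann_whitney_auc",
    "auc_confidence_interval",
    "delong_interval",
    "operating_point",
    "evaluate_all",
]


@dataclass(frozen=True)
class ReferralResult:
    subject_id: str
    group: str
    score: int
    referred: bool


@dataclass(frozen=True)
class RocPoint:
    cutoff: int
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class OperatingPoint:
    cutoff: int
    sensitivity: float
    specificity: float
    ppv: float | None
    npv: float | None
    degenerate: tuple[str, ...] = ()


@dataclass(frozen=True)
class RocAnalysis:
    comparison: str
    points: tuple[RocPoint, ...]
    auc: float
    auc_ci: tuple[float, float]
    ci_method: str
    operating: OperatingPoint
    n_cases: int
    n_controls: int

    def to_json_dict(self) -> dict:
        op = self.operating
        return {
            "comparison": self.comparison,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "ci_method": self.ci_method,
            "operating": {
                "cutoff": op.cutoff,
                "sensitivity": op.sensitivity,
                "specificity": op.specificity,
                "ppv": op.ppv,
                "npv": op.npv,
                "degenerate": list(op.degenerate),
            },
            "points": [
                {
                    "cutoff": p.cutoff,
                    "sensitivity": p.sensitivity,
                    "specificity": p.specificity,
                }
                for p in self.points
            ],
        }

    def points_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cutoff": p.cutoff,
                    "sensitivity": p.sensitivity,
                    "specificity": p.specificity,
                }
                for p in self.points
            ]
        )


def score_subjects(
    dataset: CohortDataset, scale: MergedScale
) -> tuple[ReferralResult, ...]:
    """Count positive responses on the scale items and apply the referral
    cutoff.  Rejects scales naming items absent from the cohort."""
    cols = [dataset.item_column(it) for it in scale.items]  # KeyError if absent
    mat = np.column_stack(cols)
    scores = mat.sum(axis=1).astype(int)
    return tuple(
        ReferralResult(
            subject_id=s.subject_id,
            group=s.group,
            score=int(scores[i]),
            referred=bool(scores[i] >= scale.cutoff),
        )
        for i, s in enumerate(dataset.subjects)
    )


def roc_curve(
    case_scores: Sequence[int],
    control_scores: Sequence[int],
    max_score: int,
) -> tuple[tuple[RocPoint, ...], float]:
    """Sweep the rule "score >= k" for k = 0 .. max_score + 1.

    Returns the per-cutoff (sensitivity, specificity) points and the
    trapezoidal AUC over the implied ROC polygon.
    """
    cases = np.asarray(case_scores, dtype=float)
    controls = np.asarray(control_scores, dtype=float)
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both score groups must be nonempty")
    points = []
    for k in range(0, max_score + 2):
        se = float((cases >= k).mean())
        sp = float((controls < k).mean())
        points.append(RocPoint(cutoff=k, sensitivity=se, specificity=sp))
    fpr = np.array([1.0 - p.specificity for p in points])  # decreasing in k
    tpr = np.array([p.sensitivity for p in points])
    auc = float(np.trapezoid(tpr[::-1], fpr[::-1]))
    return tuple(points), auc


def mann_whitney_auc(
    case_scores: Sequence[float], control_scores: Sequence[float]
) -> float:
    """Concordance probability P(case > control) + 0.5 P(tie), via midranks."""
    cases = np.asarray(case_scores, dtype=float)
    controls = np.asarray(control_scores, dtype=float)
    n1, n2 = len(cases), len(controls)
    if n1 == 0 or n2 == 0:
        raise ValueError("both score groups must be nonempty")
    ranks = stats.rankdata(np.concatenate([cases, controls]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n2))


def auc_confidence_interval(
    auc: float, n_cases: int, n_controls: int
) -> tuple[tuple[float, float], bool]:
    """Hanley--McNeil 95% interval, truncated to [0, 1].

    Returns (interval, degenerate); an AUC of exactly 0 or 1 yields the
    degenerate point interval with the flag set.
    """
    if n_cases < 2 or n_controls < 2:
        raise ValueError("need at least 2 subjects per class")
    if auc <= 0.0 or auc >= 1.0:
        return (float(auc), float(auc)), True
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_cases - 1.0) * (q1 - auc**2)
        + (n_controls - 1.0) * (q2 - auc**2)
    ) / (n_cases * n_controls)
    se = float(np.sqrt(var))
    z = float(stats.norm.ppf(0.975))
    return (max(0.0, auc - z * se), min(1.0, auc + z * se)), False


def delong_interval(
    case_scores: Sequence[float], control_scores: Sequence[float]
) -> tuple[float, tuple[float, float]]:
    """DeLong nonparametric AUC variance and 95% interval (flag-gated
    alternative to Hanley--McNeil)."""
    cases = np.asarray(case_scores, dtype=float)
    controls = np.asarray(control_scores, dtype=float)
    m, n = len(cases), len(controls)
    # placement values via midranks
    v10 = np.array(
        [
            ((c > controls).sum() + 0.5 * (c == controls).sum()) / n
            for c in cases
        ]
    )
    v01 = np.array(
        [
            ((cases > c).sum() + 0.5 * (cases == c).sum()) / m
            for c in controls
        ]
    )
    auc = float(v10.mean())
    var = (
        (np.var(v10, ddof=1) / m if m > 1 else 0.0)
        + (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    )
    se = float(np.sqrt(var))
    z = float(stats.norm.ppf(0.975))
    return auc, (max(0.0, auc - z * se), min(1.0, auc + z * se))


def operating_point(
    case_scores: Sequence[int],
    control_scores: Sequence[int],
    cutoff: int,
) -> OperatingPoint:
    """Se/Sp/PPV/NPV of "score >= cutoff" at the sample's case:control mix.

    PPV (NPV) is ``None``, with a degeneracy tag, when nobody is referred
    (non-referred)."""
    cases = np.asarray(case_scores, dtype=float)
    controls = np.asarray(control_scores, dtype=float)
    tp = int((cases >= cutoff).sum())
    fn = len(cases) - tp
    fp = int((controls >= cutoff).sum())
    tn = len(controls) - fp
    se = tp / len(cases)
    sp = tn / len(controls)
    degenerate = []
    if tp + fp > 0:
        ppv = tp / (tp + fp)
    else:
        ppv, degenerate = None, degenerate + ["no_referrals"]
    if tn + fn > 0:
        npv = tn / (tn + fn)
    else:
        npv, degenerate = None, degenerate + ["no_non_referrals"]
    return OperatingPoint(
        cutoff=cutoff,
        sensitivity=se,
        specificity=sp,
        ppv=ppv,
        npv=npv,
        degenerate=tuple(degenerate),
    )


_COMPARISONS = {
    "vs_diseased": ("diseased_control",),
    "vs_healthy": ("healthy_control",),
    "vs_pooled": ("diseased_control", "healthy_control"),
}


def evaluate_all(
    dataset: CohortDataset,
    scale: MergedScale,
    ci_method: str = "hanley",
) -> dict[str, RocAnalysis]:
    """One ROC analysis per control comparison present in the cohort, all at
    the scale's shared operating cutoff."""
    if ci_method not in ("hanley", "delong"):
        raise ValueError(f"unknown ci_method {ci_method!r}")
    results = score_subjects(dataset, scale)
    by_group: dict[str, list[int]] = {}
    for r in results:
        by_group.setdefault(r.group, []).append(r.score)
    if "case" not in by_group:
        raise ValueError("cohort has no cases")
    case_scores = by_group["case"]

    out: dict[str, RocAnalysis] = {}
    for name, ctrl_groups in _COMPARISONS.items():
        if not all(g in by_group for g in ctrl_groups):
            continue
        control_scores: list[int] = []
        for g in ctrl_groups:
            control_scores.extend(by_group[g])
        points, auc = roc_curve(case_scores, control_scores, scale.max_score)
        if ci_method == "delong":
            _, ci = delong_interval(case_scores, control_scores)
        else:
            ci, _ = auc_confidence_interval(
                auc, len(case_scores), len(control_scores)
            )
        op = operating_point(case_scores, control_scores, scale.cutoff)
        out[name] = RocAnalysis(
            comparison=name,
            points=points,
            auc=auc,
            auc_ci=ci,
            ci_method=ci_method,
            operating=op,
            n_cases=len(case_scores),
            n_controls=len(control_scores),
        )
    return out


def write_performance(
    analyses: dict[str, RocAnalysis], json_path: str | Path, tsv_dir: str | Path | None = None
) -> None:
    payload = {name: a.to_json_dict() for name, a in analyses.items()}
    Path(json_path).write_text(json.dumps(payload, indent=2))
    if tsv_dir is not None:
        tsv_dir = Path(tsv_dir)
        for name, a in analyses.items():
            a.points_frame().to_csv(tsv_dir / f"roc_{name}.tsv", sep="\t", index=False)
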