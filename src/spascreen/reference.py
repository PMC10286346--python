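"""Reference values from the screening instrument's development study.

The development cohort's raw item responses were never deposited, but the
published per-component reliability/validity summary, the component item
lists and the merged-scale reliability are themselves inputs: the item
reduction and referral-cutoff rules can be re-run on them exactly.  This
module records those published numbers once so the rest of the package can
recompute the retention decision, the merged-scale maximum score and the
referral cutoff from them.
"""

from __future__ import annotations

from .reliability import (
    MergedScale,
    ReliabilityReport,
    ReliabilityRow,
    merge_published_scale,
    retention_filter,
)

__all__ = [
    "PUBLISHED_COMPONENT_ITEMS",
    "PUBLISHED_GLOBAL_ALPHA",
    "published_reliability_report",
    "published_merged_scale",
]

# Item membership of the six varimax components, by text key.
PUBLISHED_COMPONENT_ITEMS: tuple[tuple[str, ...], ...] = (
    (
        "back_stiffness_gt30min",
        "night_back_pain",
        "exercise_improves_back_pain",
        "nsaid_improves_back_pain",
        "buttock_pain",
        "back_pain",
        "heel_pain",
        "urethritis",
    ),
    ("joint_swelling", "joint_pain", "joint_swelling_gt3"),
    ("psoriasis", "legs_affected", "dactylitis"),
    ("family_history_as", "red_eyes"),
    ("nodules", "anterior_chest_pain"),
    ("family_history_pso_uveitis_diarrhea", "chronic_diarrhea"),
)

# Per-component published summary: (mean, sd, alpha, convergent, discriminative)
_PUBLISHED_TABLE: tuple[tuple[float, float, float, float, float], ...] = (
    (0.98, 1.73, 0.830, 0.883, 0.895),
    (0.76, 0.97, 0.708, 0.833, 0.881),
    (0.39, 0.49, 0.109, 0.234, 0.349),
    (0.19, 0.41, 0.097, 0.106, 0.132),
    (0.18, 0.51, 0.037, 0.101, 0.123),
    (0.15, 0.42, 0.011, 0.112, 0.125),
)

# Reliability of the merged 11-item scale, as published.
PUBLISHED_GLOBAL_ALPHA = 0.669


def published_reliability_report() -> ReliabilityReport:
    """The published per-component reliability/validity table, with the
    retention rule applied to its printed values."""
    rows = []
    for c, (items, (mean, sd, alpha, conv, disc)) in enumerate(
        zip(PUBLISHED_COMPONENT_ITEMS, _PUBLISHED_TABLE), start=1
    ):
        rows.append(
            ReliabilityRow(
                component=c,
                n_items=len(items),
                items=items,
                score_mean=mean,
                score_sd=sd,
                alpha=alpha,
                convergent=conv,
                discriminative=disc,
            )
        )
    provisional = ReliabilityReport(rows=tuple(rows))
    retained = set(retention_filter(provisional))
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
    return ReliabilityReport(rows=tuple(rows))


def published_merged_scale(rounding_rule: str = "floor") -> MergedScale:
    """Merged screening scale rebuilt from the published component item lists
    and global reliability: retention, maximum score and cutoff are
    recomputed, not copied."""
    report = published_reliability_report()
    retained = report.retained_components
    component_items = [report.row(c).items for c in retained]
    return merge_published_scale(
        component_items, PUBLISHED_GLOBAL_ALPHA, rounding_rule
    )
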