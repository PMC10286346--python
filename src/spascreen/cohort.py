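"""Synthetic three-group screening cohorts with a planted two-factor structure.

The generator emulates the case--control design used to develop and validate
a spondyloarthritis (SpA) screening questionnaire: a small group of confirmed
SpA cases, a larger group of diseased (non-SpA rheumatic) controls, and a
healthy population sample, each answering the same 20 yes/no items.

Item responses follow a latent-threshold Gaussian model.  Every subject
carries two correlated latent traits -- an *axial* burden (inflammatory back
disease) and a *peripheral* burden (joint pain/swelling).  An item tagged with
a factor responds positive when

    loading * trait + sqrt(1 - loading**2) * noise  >  threshold

with standard-normal noise; untagged items are pure noise.  Thresholds are
calibrated in closed form so each item's marginal prevalence in each group
matches its target exactly, which lets the generator reproduce a printed
prevalence table while still planting a recoverable two-block correlation
structure.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GROUP_LABELS",
    "PREVALENCE_FLOOR",
    "PREVALENCE_CEIL",
    "ItemSpec",
    "GroupSpec",
    "SubjectRecord",
    "CohortDataset",
    "CohortFormatError",
    "calibrate_threshold",
    "generate_cohort",
    "default_study_specs",
    "null_study_specs",
    "write_cohort",
    "read_cohort",
]

GROUP_LABELS = ("case", "diseased_control", "healthy_control")

# Printed prevalences of exactly 0% or 100% would push the latent threshold
# to infinity; they are clamped to a representable band.
PREVALENCE_FLOOR = 0.005
PREVALENCE_CEIL = 0.995

AGE_BOUNDS = (18.0, 95.0)


@dataclass(frozen=True)
class ItemSpec:
    """One questionnaire item: its factor tag, loading and target prevalences.

    ``prevalence_by_group`` is ordered (case, diseased_control,
    healthy_control).  ``factor`` is ``"axial"``, ``"peripheral"`` or
    ``"none"``; untagged items must have zero loading.
    """

    item_id: str
    text_key: str
    factor: str
    loading: float
    prevalence_by_group: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.factor not in ("axial", "peripheral", "none"):
            raise ValueError(f"unknown factor tag {self.factor!r}")
        if not (0.0 <= self.loading < 1.0):
            raise ValueError("loading must lie in [0, 1)")
        if self.factor == "none" and self.loading != 0.0:
            raise ValueError("untagged items must have loading 0")
        for p in self.prevalence_by_group:
            if not (0.0 <= p <= 1.0):
                raise ValueError("prevalences must lie in [0, 1]")


@dataclass(frozen=True)
class GroupSpec:
    """One study group: size, demographics and latent-trait mean offsets.

    ``onset_lag_mean`` is the mean of the exponential lag between disease
    onset and interview; ``None`` means age-at-onset is not recorded for the
    group (healthy subjects have no onset).
    """

    group: str
    n: int
    age_mean: float
    age_sd: float
    male_fraction: float
    axial_shift: float = 0.0
    peripheral_shift: float = 0.0
    onset_lag_mean: float | None = None

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("group size must be positive")
        if not (0.0 <= self.male_fraction <= 1.0):
            raise ValueError("male_fraction must lie in [0, 1]")
        if self.age_sd <= 0:
            raise ValueError("age_sd must be positive")


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str
    age: float
    sex: str
    age_at_onset: float | None
    responses: tuple[int, ...]


@dataclass(frozen=True)
class CohortDataset:
    """Subject-level item responses plus the item metadata; the pipeline input."""

    subjects: tuple[SubjectRecord, ...]
    items: tuple[ItemSpec, ...]
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject_id in cohort")
        p = len(self.items)
        for s in self.subjects:
            if len(s.responses) != p:
                raise ValueError(
                    f"subject {s.subject_id} has {len(s.responses)} responses, expected {p}"
                )

    # -- convenience accessors -------------------------------------------------

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)

    @property
    def groups(self) -> tuple[str, ...]:
        seen: list[str] = []
        for s in self.subjects:
            if s.group not in seen:
                seen.append(s.group)
        return tuple(seen)

    def group_sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s in self.subjects:
            out[s.group] = out.get(s.group, 0) + 1
        return out

    def response_matrix(self, groups: Iterable[str] | None = None) -> np.ndarray:
        """n x p integer 0/1 matrix, optionally restricted to some groups."""
        keep = None if groups is None else set(groups)
        rows = [
            s.responses for s in self.subjects if keep is None or s.group in keep
        ]
        return np.asarray(rows, dtype=float).reshape(len(rows), len(self.items))

    def item_column(self, item_id: str, group: str | None = None) -> np.ndarray:
        """Responses of one item (addressable by item_id or text_key)."""
        try:
            j = self.item_ids.index(item_id)
        except ValueError:
            keys = tuple(it.text_key for it in self.items)
            if item_id in keys:
                j = keys.index(item_id)
            else:
                raise KeyError(f"unknown item {item_id!r}") from None
        rows = [
            s.responses[j]
            for s in self.subjects
            if group is None or s.group == group
        ]
        return np.asarray(rows, dtype=float)

    def ages(self, group: str) -> np.ndarray:
        return np.asarray([s.age for s in self.subjects if s.group == group])

    def onsets(self, group: str) -> np.ndarray:
        vals = [
            s.age_at_onset
            for s in self.subjects
            if s.group == group and s.age_at_onset is not None
        ]
        return np.asarray(vals, dtype=float)

    def same_data(self, other: "CohortDataset") -> bool:
        """Equality of subjects and items, ignoring provenance."""
        return self.subjects == other.subjects and self.items == other.items


class CohortFormatError(ValueError):
    """A cohort CSV violated the file contract; message names row/column."""


def clamp_prevalence(p: float) -> float:
    return min(max(p, PREVALENCE_FLOOR), PREVALENCE_CEIL)


def calibrate_threshold(
    target_prevalence: float, loading: float, latent_shift: float
) -> float:
    """Latent threshold giving an exact marginal prevalence.

    Under ``response = 1 iff loading*(shift + Z1) + sqrt(1-loading^2)*Z2 > t``
    the left side is N(loading*shift, 1), so
    ``t = loading*shift + Phi^-1(1 - target)``.
    """
    if not (0.0 < target_prevalence < 1.0):
        raise ValueError(
            "target_prevalence must lie strictly in (0, 1); clamp degenerate "
            f"values to [{PREVALENCE_FLOOR}, {PREVALENCE_CEIL}] first"
        )
    return loading * latent_shift + float(stats.norm.ppf(1.0 - target_prevalence))


def generate_cohort(
    groups: Sequence[GroupSpec],
    items: Sequence[ItemSpec],
    seed: int,
    factor_corr: float = 0.3,
) -> CohortDataset:
    """Draw a seeded cohort under the latent-threshold model.

    Per subject: bivariate-normal (axial, peripheral) traits with unit
    variances, correlation ``factor_corr`` and group-specific mean shifts;
    ages truncated-normal on [18, 95]; sex Bernoulli(male_fraction);
    age-at-onset = age minus an exponential lag where the group records onset.
    Deterministic given ``seed``.
    """
    if not groups:
        raise ValueError("at least one group is required")
    if not items:
        raise ValueError("at least one item is required")
    if not (-1.0 < factor_corr < 1.0):
        raise ValueError("factor_corr must lie in (-1, 1)")

    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, factor_corr], [factor_corr, 1.0]])
    chol = np.linalg.cholesky(cov)

    subjects: list[SubjectRecord] = []
    counter = 0
    for g in groups:
        n = g.n
        z = rng.standard_normal((n, 2)) @ chol.T
        traits = z + np.array([g.axial_shift, g.peripheral_shift])

        lo, hi = AGE_BOUNDS
        a, b = (lo - g.age_mean) / g.age_sd, (hi - g.age_mean) / g.age_sd
        ages = stats.truncnorm.rvs(
            a, b, loc=g.age_mean, scale=g.age_sd, size=n, random_state=rng
        )
        sexes = np.where(rng.random(n) < g.male_fraction, "M", "F")
        if g.onset_lag_mean is not None:
            lags = rng.exponential(g.onset_lag_mean, size=n)
            onsets = np.maximum(ages - lags, 1.0)
        else:
            onsets = None

        gi = GROUP_LABELS.index(g.group) if g.group in GROUP_LABELS else None
        resp = np.empty((n, len(items)), dtype=int)
        for j, item in enumerate(items):
            if gi is None:
                target = item.prevalence_by_group[0]
            else:
                target = item.prevalence_by_group[gi]
            target = clamp_prevalence(target)
            if item.factor == "axial":
                trait = traits[:, 0]
                shift = g.axial_shift
            elif item.factor == "peripheral":
                trait = traits[:, 1]
                shift = g.peripheral_shift
            else:
                trait = np.zeros(n)
                shift = 0.0
            t = calibrate_threshold(target, item.loading, shift)
            noise = rng.standard_normal(n)
            y = item.loading * trait + math.sqrt(1.0 - item.loading**2) * noise
            resp[:, j] = (y > t).astype(int)

        for i in range(n):
            counter += 1
            subjects.append(
                SubjectRecord(
                    subject_id=f"S{counter:04d}",
                    group=g.group,
                    age=float(ages[i]),
                    sex=str(sexes[i]),
                    age_at_onset=float(onsets[i]) if onsets is not None else None,
                    responses=tuple(int(v) for v in resp[i]),
                )
            )

    return CohortDataset(
        subjects=tuple(subjects),
        items=tuple(items),
        provenance={
            "source": "generator",
            "seed": int(seed),
            "factor_corr": float(factor_corr),
            "groups": [g.group for g in groups],
            "n_items": len(items),
        },
    )


# -- default parameterisation ----------------------------------------------
#
# Group sizes, demographics and per-group item prevalences reproduce the
# instrument's development cohort (50 SpA cases, 150 non-SpA rheumatic
# controls, 200 healthy subjects).  Factor tags mark the axial block (8
# items: inflammatory back pain features, buttock/heel pain, NSAID response,
# urethritis) and the peripheral block (3 joint items) that the validated
# instrument retains.  Loadings are generator parameters, not estimates.
# 0.80 for tagged items plants a recoverable two-block structure while
# keeping item responses conditionally diverse enough that summed scores
# discriminate well (near-unit loadings make a block behave like a single
# item, fattening the control-score tail and degrading ROC performance).
# The very rare urethritis item gets 0.98: when present it is an almost
# deterministic marker of the axial trait, which keeps its component
# assignment as stable as a 2.5%-prevalence item allows at n = 400.

_BLOCK_LOADING = 0.80
_RARE_MARKER_LOADING = 0.98

_ITEM_TABLE: list[tuple[str, str, float, float, float, float]] = [
    # text_key, factor, loading, prevalence in (case, diseased, healthy)
    ("joint_pain", "peripheral", _BLOCK_LOADING, 0.460, 0.893, 0.140),
    ("joint_swelling", "peripheral", _BLOCK_LOADING, 0.460, 0.347, 0.015),
    ("joint_swelling_gt3", "peripheral", _BLOCK_LOADING, 0.120, 0.193, 0.035),
    ("legs_affected", "none", 0.0, 0.140, 0.193, 0.170),
    ("back_pain", "axial", _BLOCK_LOADING, 0.840, 0.487, 0.205),
    ("back_stiffness_gt30min", "axial", _BLOCK_LOADING, 0.860, 0.047, 0.005),
    ("night_back_pain", "axial", _BLOCK_LOADING, 0.780, 0.020, 0.040),
    ("exercise_improves_back_pain", "axial", _BLOCK_LOADING, 0.760, 0.027, 0.090),
    ("nsaid_improves_back_pain", "axial", _BLOCK_LOADING, 0.860, 0.120, 0.135),
    ("anterior_chest_pain", "none", 0.0, 0.040, 0.000, 0.050),
    ("buttock_pain", "axial", _BLOCK_LOADING, 0.580, 0.007, 0.040),
    ("red_eyes", "none", 0.0, 0.280, 0.000, 0.120),
    ("heel_pain", "axial", _BLOCK_LOADING, 0.400, 0.020, 0.050),
    ("chronic_diarrhea", "none", 0.0, 0.040, 0.000, 0.010),
    ("urethritis", "axial", _RARE_MARKER_LOADING, 0.180, 0.000, 0.005),
    ("psoriasis", "none", 0.0, 0.020, 0.000, 0.000),
    ("family_history_as", "none", 0.0, 0.000, 0.000, 0.005),
    ("family_history_pso_uveitis_diarrhea", "none", 0.0, 0.000, 0.000, 0.005),
    ("nodules", "none", 0.0, 0.000, 0.007, 0.020),
    ("dactylitis", "none", 0.0, 0.080, 0.007, 0.010),
]


def default_study_specs() -> tuple[tuple[GroupSpec, ...], tuple[ItemSpec, ...]]:
    """Group and item specs reproducing the development cohort's structure.

    Returns the three groups (n = 50 / 150 / 200 with their printed age and
    sex distributions) and the 20 items with their per-group "yes" fractions.
    """
    groups = (
        GroupSpec(
            group="case",
            n=50,
            age_mean=41.8,
            age_sd=14.4,
            male_fraction=0.56,
            axial_shift=1.0,
            peripheral_shift=0.5,
            onset_lag_mean=4.3,
        ),
        GroupSpec(
            group="diseased_control",
            n=150,
            age_mean=60.0,
            age_sd=12.5,
            male_fraction=0.287,
            axial_shift=0.0,
            peripheral_shift=0.5,
            onset_lag_mean=4.3,
        ),
        GroupSpec(
            group="healthy_control",
            n=200,
            age_mean=33.1,
            age_sd=12.4,
            male_fraction=0.58,
            axial_shift=0.0,
            peripheral_shift=0.0,
            onset_lag_mean=None,
        ),
    )
    items = tuple(
        ItemSpec(
            item_id=f"q{j + 1:02d}",
            text_key=key,
            factor=factor,
            loading=loading,
            prevalence_by_group=(pc, pd, ph),
        )
        for j, (key, factor, loading, pc, pd, ph) in enumerate(_ITEM_TABLE)
    )
    return groups, items


def null_study_specs(
    prevalence: float = 0.3,
) -> tuple[tuple[GroupSpec, ...], tuple[ItemSpec, ...]]:
    """No-effect variant: same design, identical prevalences in all groups,
    no latent structure.  Used for type-I-error checks."""
    groups, items = default_study_specs()
    groups = tuple(
        replace(g, axial_shift=0.0, peripheral_shift=0.0) for g in groups
    )
    items = tuple(
        replace(
            it,
            factor="none",
            loading=0.0,
            prevalence_by_group=(prevalence, prevalence, prevalence),
        )
        for it in items
    )
    return groups, items


# -- CSV round trip ---------------------------------------------------------

_FIXED_COLUMNS = ["subject_id", "group", "age", "sex", "age_at_onset"]


def write_cohort(dataset: CohortDataset, path: str | Path) -> Path:
    """Write the cohort CSV (header ``subject_id,group,age,sex,age_at_onset,q01..``)."""
    path = Path(path)
    qcols = list(dataset.item_ids)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_FIXED_COLUMNS + qcols)
        for s in dataset.subjects:
            onset = "" if s.age_at_onset is None else repr(s.age_at_onset)
            writer.writerow(
                [s.subject_id, s.group, repr(s.age), s.sex, onset]
                + list(s.responses)
            )
    return path


def read_cohort(
    path: str | Path, items: Sequence[ItemSpec] | None = None
) -> CohortDataset:
    """Read a cohort CSV, validating the file contract row by row.

    If ``items`` is omitted the file must carry the standard 20-question
    instrument (columns q01..q20), whose default item metadata is assumed.
    """
    path = Path(path)
    expected_q = (
        [it.item_id for it in items]
        if items is not None
        else [f"q{j:02d}" for j in range(1, 21)]
    )
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise CohortFormatError(f"{path}: empty file") from None
        missing = [c for c in _FIXED_COLUMNS + expected_q if c not in header]
        if missing:
            raise CohortFormatError(
                f"{path}: missing columns: {', '.join(missing)}"
            )
        idx = {c: header.index(c) for c in _FIXED_COLUMNS + expected_q}

        subjects: list[SubjectRecord] = []
        for rownum, row in enumerate(reader, start=2):
            if not row or all(not cell for cell in row):
                continue
            group = row[idx["group"]]
            if group not in GROUP_LABELS:
                raise CohortFormatError(
                    f"{path}: row {rownum}: unknown group {group!r}"
                )
            try:
                age = float(row[idx["age"]])
            except ValueError:
                raise CohortFormatError(
                    f"{path}: row {rownum}: non-numeric age"
                ) from None
            if age <= 0:
                raise CohortFormatError(f"{path}: row {rownum}: age must be > 0")
            sex = row[idx["sex"]]
            if sex not in ("M", "F"):
                raise CohortFormatError(
                    f"{path}: row {rownum}: sex must be M or F, got {sex!r}"
                )
            onset_cell = row[idx["age_at_onset"]]
            onset = None if onset_cell == "" else float(onset_cell)
            if onset is not None and onset > age:
                raise CohortFormatError(
                    f"{path}: row {rownum}: age_at_onset exceeds age"
                )
            responses: list[int] = []
            for q in expected_q:
                cell = row[idx[q]]
                if cell not in ("0", "1"):
                    raise CohortFormatError(
                        f"{path}: row {rownum}, column {q}: response must be "
                        f"0 or 1, got {cell!r}"
                    )
                responses.append(int(cell))
            subjects.append(
                SubjectRecord(
                    subject_id=row[idx["subject_id"]],
                    group=group,
                    age=age,
                    sex=sex,
                    age_at_onset=onset,
                    responses=tuple(responses),
                )
            )

    if items is None:
        items = default_study_specs()[1]

    return CohortDataset(
        subjects=tuple(subjects),
        items=tuple(items),
        provenance={"source": "file", "path": str(path)},
    )
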