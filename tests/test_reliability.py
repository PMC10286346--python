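"""Cronbach's alpha, scaling success, retention and the referral cutoff."""

import numpy as np
import pytest

from spascreen.cohort import CohortDataset, ItemSpec, SubjectRecord
from spascreen.factor import ComponentAssignment
from spascreen.reliability import (
    ReliabilityReport,
    ReliabilityRow,
    alpha_from_matrix,
    component_reliability_report,
    cronbach_alpha,
    item_scale_correlations,
    merge_scale,
    referral_cutoff,
    retention_filter,
    scaling_success,
)
from spascreen.reference import (
    PUBLISHED_GLOBAL_ALPHA,
    published_merged_scale,
    published_reliability_report,
)


def binary_cohort(matrix):
    matrix = np.asarray(matrix, dtype=int)
    items = tuple(
        ItemSpec(f"q{j + 1:02d}", f"k{j}", "none", 0.0, (0.5, 0.5, 0.5))
        for j in range(matrix.shape[1])
    )
    subjects = tuple(
        SubjectRecord(f"S{i}", "case", 40.0, "M", None, tuple(row))
        for i, row in enumerate(matrix)
    )
    return CohortDataset(subjects=subjects, items=items)


def assignment_of(items_by_component, all_items):
    assignments = {}
    for comp, items in items_by_component.items():
        for it in items:
            assignments[it] = (comp, 0.8)
    return ComponentAssignment(
        assignments=assignments,
        unassigned=tuple(i for i in all_items if i not in assignments),
        loading_threshold=0.36,
        n_components=max(items_by_component),
        items=tuple(all_items),
    )


class TestCronbachAlpha:
    def test_duplicated_items_give_one(self, rng):
        x = (rng.random(100) < 0.5).astype(int)
        ds = binary_cohort(np.column_stack([x, x, x]))
        assert cronbach_alpha(ds, ["q01", "q02", "q03"]) == pytest.approx(1.0)

    def test_compound_symmetry_matches_spearman_brown(self):
        # equicorrelated continuous items, r = 0.3, p = 8, n = 2000:
        # alpha must approach 8r / (1 + 7r) = 0.774
        rng = np.random.default_rng(5)
        n, p, r = 2000, 8, 0.3
        common = rng.standard_normal((n, 1))
        x = np.sqrt(r) * common + np.sqrt(1 - r) * rng.standard_normal((n, p))
        assert alpha_from_matrix(x) == pytest.approx(8 * r / (1 + 7 * r), abs=0.02)

    def test_independent_items_give_near_zero(self):
        rng = np.random.default_rng(5)
        x = (rng.random((4000, 6)) < 0.5).astype(int)
        assert abs(alpha_from_matrix(x)) < 0.05

    def test_degenerate_inputs_rejected(self, rng):
        x = (rng.random(50) < 0.5).astype(int)
        ds = binary_cohort(np.column_stack([x, 1 - x]))
        with pytest.raises(ValueError):  # total score constant
            cronbach_alpha(ds, ["q01", "q02"])
        with pytest.raises(ValueError):  # single item
            cronbach_alpha(ds, ["q01"])

    def test_noise_item_never_helps_compound_symmetric_scale(self):
        # appending an uncorrelated item dilutes internal consistency
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n, p, r = 1000, 6, 0.4
            common = rng.standard_normal((n, 1))
            x = np.sqrt(r) * common + np.sqrt(1 - r) * rng.standard_normal((n, p))
            noise = rng.standard_normal((n, 1))
            assert alpha_from_matrix(np.hstack([x, noise])) < alpha_from_matrix(x)


class TestItemScaleCorrelations:
    def test_duplicated_pair_scale_gives_corrected_one(self, rng):
        x = (rng.random(200) < 0.5).astype(int)
        y = (rng.random(200) < 0.5).astype(int)
        ds = binary_cohort(np.column_stack([x, x, y]))
        asg = assignment_of({1: ("q01", "q02"), 2: ("q03",)}, ds.item_ids)
        cors = item_scale_correlations(ds, asg)
        # own scale of q01 minus q01 itself is exactly its duplicate q02
        assert cors.own("q01") == pytest.approx(1.0)

    def test_independent_item_uncorrelated_with_scales(self):
        rng = np.random.default_rng(3)
        n = 5000
        x = (rng.random((n, 4)) < 0.5).astype(int)
        ds = binary_cohort(x)
        asg = assignment_of({1: ("q01", "q02"), 2: ("q03", "q04")}, ds.item_ids)
        cors = item_scale_correlations(ds, asg)
        assert abs(cors.cross("q01", 2)) < 3 / np.sqrt(n)

    def test_overlap_correction_lowers_own_correlation(self, default_cohort):
        from spascreen.factor import (
            assign_items,
            correlation_matrix,
            extract_components,
            rotate_solution,
        )

        asg = assign_items(
            rotate_solution(extract_components(correlation_matrix(default_cohort)))
        )
        cors = item_scale_correlations(default_cohort, asg)
        for item, (comp, _) in asg.assignments.items():
            own_items = asg.component_items(comp)
            if len(own_items) < 3:
                continue
            total = np.column_stack(
                [default_cohort.item_column(i) for i in own_items]
            ).sum(axis=1)
            x = default_cohort.item_column(item)
            uncorrected = np.corrcoef(x, total)[0, 1]
            assert uncorrected >= cors.own(item) - 1e-12


class TestScalingSuccess:
    def test_perfect_simple_structure(self, rng):
        common1 = (rng.random(500) < 0.5).astype(int)
        common2 = (rng.random(500) < 0.5).astype(int)
        ds = binary_cohort(np.column_stack([common1, common1, common2, common2]))
        asg = assignment_of({1: ("q01", "q02"), 2: ("q03", "q04")}, ds.item_ids)
        success = scaling_success(item_scale_correlations(ds, asg))
        assert success[1] == (1.0, 1.0)
        assert success[2] == (1.0, 1.0)

    def test_uncorrelated_items_fail_convergence(self):
        rng = np.random.default_rng(9)
        ds = binary_cohort((rng.random((2000, 4)) < 0.5).astype(int))
        asg = assignment_of({1: ("q01", "q02"), 2: ("q03", "q04")}, ds.item_ids)
        success = scaling_success(item_scale_correlations(ds, asg))
        assert success[1][0] == 0.0

    def test_single_component_has_no_discriminative_part(self, rng):
        x = (rng.random(100) < 0.5).astype(int)
        ds = binary_cohort(np.column_stack([x, x]))
        asg = assignment_of({1: ("q01", "q02")}, ds.item_ids)
        success = scaling_success(item_scale_correlations(ds, asg))
        assert success[1][1] is None


class TestRetention:
    def test_published_values_retain_first_two_components(self):
        report = published_reliability_report()
        assert retention_filter(report) == (1, 2)
        assert report.retained_components == (1, 2)

    def test_boundary_is_inclusive(self):
        rows = tuple(
            ReliabilityRow(component=c, n_items=2, items=(f"a{c}", f"b{c}"),
                           score_mean=1.0, score_sd=1.0, alpha=0.70,
                           convergent=0.70, discriminative=0.70)
            for c in (1, 2)
        )
        assert retention_filter(ReliabilityReport(rows=rows)) == (1, 2)

    def test_empty_report_gives_empty_set(self):
        assert retention_filter(ReliabilityReport(rows=())) == ()

    def test_monotone_in_floor(self):
        report = published_reliability_report()
        previous = set(retention_filter(report, floor=0.0))
        for floor in (0.2, 0.5, 0.7, 0.85, 1.0):
            current = set(retention_filter(report, floor=floor))
            assert current <= previous
            previous = current


class TestReferralCutoff:
    def test_published_reliability_gives_seven_of_eleven(self):
        assert referral_cutoff(0.669, 11) == 7

    @pytest.mark.parametrize("alpha,expected", [(1.0, 11), (0.0, 0)])
    def test_extreme_reliabilities(self, alpha, expected):
        assert referral_cutoff(alpha, 11) == expected

    def test_ceil_alternative(self):
        assert referral_cutoff(0.669, 11, rule="ceil") == 8

    def test_monotone_in_alpha_and_score(self):
        cuts = [referral_cutoff(a, 11) for a in np.linspace(0, 1, 21)]
        assert all(a <= b for a, b in zip(cuts, cuts[1:]))
        cuts = [referral_cutoff(0.669, m) for m in range(1, 20)]
        assert all(a <= b for a, b in zip(cuts, cuts[1:]))


class TestMergedScale:
    def test_published_merge_has_eleven_items_cutoff_seven(self):
        scale = published_merged_scale()
        assert scale.max_score == 11
        assert len(scale.items) == 11
        assert scale.global_alpha == PUBLISHED_GLOBAL_ALPHA
        assert scale.cutoff == 7
        # axial items first, then the peripheral triplet
        assert scale.items[0] == "back_stiffness_gt30min"
        assert scale.items[8:] == (
            "joint_swelling", "joint_pain", "joint_swelling_gt3",
        )

    def test_merge_on_synthetic_cohort(self, default_cohort):
        from spascreen.factor import (
            assign_items,
            correlation_matrix,
            extract_components,
            rotate_solution,
        )

        asg = assign_items(
            rotate_solution(extract_components(correlation_matrix(default_cohort)))
        )
        rel = component_reliability_report(default_cohort, asg)
        retained = rel.retained_components
        assert retained  # the planted axial block must survive
        scale = merge_scale(default_cohort, retained, asg)
        assert scale.max_score == len(scale.items)
        assert scale.cutoff == int(np.floor(scale.global_alpha * scale.max_score))

    def test_merge_requires_retained_components(self, default_cohort):
        asg = assignment_of({1: ("q01", "q02")}, default_cohort.item_ids)
        with pytest.raises(ValueError):
            merge_scale(default_cohort, [], asg)


class TestAgainstPingouin:
    def test_alpha_cross_checked_against_independent_implementation(self, default_cohort):
        import pandas as pd
        import pingouin as pg

        items = [f"q{j:02d}" for j in range(5, 10)]
        df = pd.DataFrame({it: default_cohort.item_column(it) for it in items})
        ours = cronbach_alpha(default_cohort, items)
        theirs = pg.cronbach_alpha(data=df)[0]
        assert ours == pytest.approx(theirs, abs=1e-10)
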