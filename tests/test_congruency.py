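"""Congruency evaluation: tables, percentages, Yates chi-square, skip rules."""

import math

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from modadvice.advice import BA, EPA, EXPOSURE, SLEEP, WELLNESS, ModuleId
from modadvice.config import RunConfig
from modadvice.congruency import (
    ChiSquareResult,
    ContingencyTable2x2,
    EvaluationError,
    ParticipantRecord,
    advice_cardinality_summary,
    cross_tabulate,
    evaluation_report,
    frequency_table,
    percentage,
    yates_chi_square,
)


def make_record(pid, interview=(), questionnaires=(), network=(), chosen=(BA, EPA, SLEEP)):
    return ParticipantRecord(
        pid,
        frozenset(interview),
        frozenset(questionnaires),
        frozenset(network),
        frozenset(chosen),
    )


@pytest.fixture
def small_cohort():
    return (
        make_record("a", interview={BA}, questionnaires={SLEEP}, network={EPA},
                    chosen=(BA, EPA, SLEEP)),
        make_record("b", interview={BA, EXPOSURE}, questionnaires={WELLNESS},
                    network=set(), chosen=(BA, EXPOSURE, WELLNESS)),
        make_record("c", interview={EXPOSURE}, questionnaires=set(), network={EXPOSURE},
                    chosen=(EXPOSURE, EPA, WELLNESS)),
        make_record("d", interview={BA}, questionnaires={SLEEP, EPA, WELLNESS},
                    network={SLEEP}, chosen=(BA, SLEEP, WELLNESS)),
    )


class TestPercentages:
    @pytest.mark.parametrize(
        "count, total, expected",
        [(62, 74, 83.78), (67, 74, 90.54), (11, 74, 14.86), (43, 74, 58.11),
         (52, 74, 70.27), (0, 74, 0.0)],
    )
    def test_half_up_to_two_decimals(self, count, total, expected):
        assert percentage(count, total) == expected

    def test_percentages_recover_counts_within_rounding(self, small_cohort):
        freq = frequency_table(small_cohort)
        n = len(small_cohort)
        for axis in freq.values():
            for entry in axis.values():
                assert abs(entry["percent"] / 100 * n - entry["count"]) <= 0.005 * n


class TestFrequencyTable:
    def test_counts_match_membership(self, small_cohort):
        freq = frequency_table(small_cohort)
        assert freq["interview"]["BEHAVIORAL_ACTIVATION"]["count"] == 3
        assert freq["interview"]["EXPOSURE"]["count"] == 2
        assert freq["questionnaires"]["SLEEP"]["count"] == 2
        assert freq["chosen"]["WELLNESS"]["count"] == 3
        # interview axis never tabulates questionnaire-only modules
        assert set(freq["interview"]) == {"BEHAVIORAL_ACTIVATION", "EXPOSURE"}

    def test_empty_cohort_rejected(self):
        with pytest.raises(EvaluationError):
            frequency_table(())


class TestCardinalitySummary:
    def test_disjoint_counts_sum_to_cohort(self, small_cohort):
        card = advice_cardinality_summary(small_cohort)
        total = sum(card[k]["count"] for k in ("below_3", "exactly_3", "above_3"))
        assert total == len(small_cohort)
        assert card["above_3"]["count"] == 1  # participant d (4 advised)
        assert card["below_3"]["count"] == 1  # participant c (1 advised)

    def test_all_exactly_three(self):
        cohort = tuple(
            make_record(str(i), interview={BA}, questionnaires={SLEEP}, network={EPA})
            for i in range(5)
        )
        card = advice_cardinality_summary(cohort)
        assert (card["below_3"]["count"], card["exactly_3"]["count"],
                card["above_3"]["count"]) == (0, 5, 0)

    def test_wellness_exclusion_changes_the_union(self):
        cohort = (
            make_record("a", interview={BA}, questionnaires={SLEEP, WELLNESS},
                        network={EPA}),
        )
        assert advice_cardinality_summary(cohort)["above_3"]["count"] == 1
        assert (
            advice_cardinality_summary(cohort, exclude_wellness=True)["exactly_3"]["count"]
            == 1
        )


class TestCrossTabulate:
    def test_single_participant_single_cell(self):
        cohort = (make_record("a", interview={BA}, network={BA}),)
        tab = cross_tabulate(cohort, BA, "interview", "network")
        assert tab.cells == (0, 0, 0, 1)

    def test_cells_sum_to_cohort_size(self, small_cohort):
        tab = cross_tabulate(small_cohort, EXPOSURE, "interview", "network")
        assert tab.total == len(small_cohort)

    def test_module_without_axis_rejected(self, small_cohort):
        with pytest.raises(EvaluationError, match="no questionnaires axis"):
            cross_tabulate(small_cohort, BA, "questionnaires", "network")
        with pytest.raises(EvaluationError, match="unknown axis"):
            cross_tabulate(small_cohort, BA, "interview", "diary")


class TestYatesChiSquare:
    @pytest.mark.parametrize(
        "cells, stat",
        [((12, 8, 44, 10), 2.584), ((26, 29, 6, 13), 0.850)],
    )
    def test_published_statistics(self, cells, stat):
        res = yates_chi_square(cells)
        assert res.performed
        assert res.statistic == pytest.approx(stat, abs=1e-3)
        assert res.df == 1

    @pytest.mark.parametrize("cells", [(7, 0, 63, 4), (46, 5, 22, 1)])
    def test_skip_rule_for_low_cells(self, cells):
        res = yates_chi_square(cells)
        assert not res.performed
        assert res.statistic is None and res.p_value is None
        assert "below minimum" in res.skip_reason

    def test_zero_margin_degenerate(self):
        res = yates_chi_square((5, 5, 0, 0), min_cell=0)
        assert not res.performed
        assert res.skip_reason == "zero margin"

    def test_matches_scipy_oracle_on_random_tables(self, rng):
        for _ in range(100):
            cells = tuple(int(x) for x in rng.integers(2, 60, size=4))
            res = yates_chi_square(cells)
            stat, p, dof, _ = chi2_contingency(
                np.array(cells).reshape(2, 2), correction=True
            )
            assert res.performed and dof == 1
            assert res.statistic == pytest.approx(stat, abs=1e-10)
            assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_correction_never_increases_the_statistic(self, rng):
        for _ in range(100):
            obs = rng.integers(2, 40, size=4).astype(float).reshape(2, 2)
            expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
            pearson = ((obs - expected) ** 2 / expected).sum()
            res = yates_chi_square(tuple(int(x) for x in obs.ravel()))
            assert res.statistic <= pearson + 1e-12

    def test_invariant_under_simultaneous_label_swap(self):
        a = yates_chi_square((12, 8, 44, 10))
        b = yates_chi_square((10, 44, 8, 12))  # both row and column flipped
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)

    def test_p_value_matches_erfc_closed_form(self, rng):
        # independent 1-df upper tail: P(X > x) = erfc(sqrt(x/2))
        for _ in range(50):
            cells = tuple(int(x) for x in rng.integers(2, 60, size=4))
            res = yates_chi_square(cells)
            assert res.p_value == pytest.approx(
                math.erfc(math.sqrt(res.statistic / 2)), abs=1e-8
            )

    def test_rejects_negative_or_fractional_cells(self):
        with pytest.raises(EvaluationError):
            yates_chi_square((-1, 5, 5, 5))


class TestEvaluationReport:
    def test_report_shape_and_determinism(self, small_cohort):
        rep = evaluation_report(small_cohort)
        assert rep["n_participants"] == 4
        assert {e["module"] for e in rep["source_vs_network"]} == {
            m.value for m in (BA, EXPOSURE, EPA, SLEEP, WELLNESS)
        }
        assert rep == evaluation_report(small_cohort)

    def test_wellness_exclusion_footnote(self, small_cohort):
        cfg = RunConfig(exclude_wellness=True)
        rep = evaluation_report(small_cohort, cfg)
        assert WELLNESS.value not in {e["module"] for e in rep["source_vs_network"]}
        assert any("Wellness" in n for n in rep.get("footnotes", []))
        # frequency table still shows Wellness descriptively
        assert WELLNESS.value in rep["frequencies"]["questionnaires"]

    def test_small_cohort_tests_skipped_not_crashed(self, small_cohort):
        rep = evaluation_report(small_cohort)
        for entry in rep["source_vs_network"]:
            cs = entry["chi_square"]
            assert cs["performed"] in (True, False)
            if not cs["performed"]:
                assert cs["skip_reason"]
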