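"""Cohort fixture counts, proportions, Fisher's exact test and rankers."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

import resiflex as rf
from resiflex.cohort import (ATTRIBUTES, score_chi2, score_info_gain,
                             score_relieff, score_symmetrical_uncertainty)
from resiflex.datasets import DELE746, L858R, NON_LRE
from resiflex.errors import CohortValidationError, ResiflexError


def fisher_two_sided_oracle(table):
    """Exact-rational enumeration of the two-sided point-probability rule."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c), denom)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
        if p <= p_obs:
            total += p
    return float(total)


@pytest.fixture(scope="module")
def cohort():
    return rf.paper_cohort()


class TestPaperFixture:
    def test_sixty_eight_valid_records(self, cohort):
        assert len(cohort) == 68
        assert rf.validate_cohort(cohort) == []
        assert int(cohort.t790m.sum()) == 27

    def test_mutation_tki_table_cells(self, cohort):
        tab = rf.mutation_tki_table(cohort)
        expect = {
            ("gefitinib", DELE746): (17, 28, 60.7),
            ("gefitinib", NON_LRE): (0, 3, 0.0),
            ("gefitinib", L858R): (7, 23, 30.4),
            ("gefitinib", "overall"): (24, 54, 44.4),
            ("erlotinib", DELE746): (4, 9, 44.4),
            ("erlotinib", NON_LRE): (0, 1, 0.0),
            ("erlotinib", L858R): (0, 5, 0.0),
            ("erlotinib", "overall"): (4, 15, 26.7),
            ("afatinib", DELE746): (4, 6, 66.7),
            ("afatinib", NON_LRE): (0, 0, None),
            ("afatinib", L858R): (1, 5, 20.0),
            ("afatinib", "overall"): (5, 11, 45.5),
            ("overall", DELE746): (19, 31, 61.3),
            ("overall", NON_LRE): (0, 3, 0.0),
            ("overall", L858R): (8, 31, 25.8),
            ("overall", "overall"): (27, 65, 41.5),
        }
        for (tki, mut), (k, n, pct) in expect.items():
            p = tab[tki][mut]
            assert (p.numerator, p.denominator) == (k, n), (tki, mut)
            assert p.percent_rounded == pct, (tki, mut)

    def test_results_proportions(self, cohort):
        rp = rf.results_proportions(cohort)
        checks = [
            (rp.overall, 27, 68, 39.7),
            (rp.bone, 21, 34, 61.8),
            (rp.no_bone, 6, 34, 17.6),
            (rp.bone_share_of_positive, 21, 27, 77.8),
            (rp.bone_and_dele746, 15, 18, 83.3),
            (rp.single_site_negative, 14, 15, 93.3),
        ]
        for p, k, n, pct in checks:
            assert (p.numerator, p.denominator, p.percent_rounded) == (k, n, pct)

    def test_bone_met_contingency_orientation(self, cohort):
        table = rf.build_contingency(cohort, "bone_met")
        assert table.counts.tolist() == [[21, 13], [6, 28]]
        assert table.row_labels == (True, False)


class TestProportionRounding:
    @pytest.mark.parametrize("k,n,expected", [
        (17, 28, 60.7),   # printed mutation x TKI cell
        (0, 3, 0.0),
        (1, 3, 33.3),
        (5, 11, 45.5),    # 45.4545.. rounds up
        (1, 8, 12.5),     # exact .5 boundary stays (round-half-up)
    ])
    def test_round_half_up_one_decimal(self, k, n, expected):
        assert rf.Proportion(k, n).percent_rounded == expected

    def test_empty_denominator_is_blank(self):
        p = rf.Proportion(0, 0)
        assert p.percent_rounded is None and str(p) == "0/0"


class TestFisherExact:
    def _table(self, counts):
        return rf.ContingencyTable(np.asarray(counts), ("r1", "r2"),
                                   ("c1", "c2"))

    def test_balanced_table_is_one(self):
        assert rf.fisher_exact_two_sided(self._table([[5, 5], [5, 5]])) == 1.0

    def test_bone_met_table_to_one_significant_figure(self):
        p = rf.fisher_exact_two_sided(self._table([[21, 13], [6, 28]]))
        assert float(f"{p:.0e}") == 4e-4

    def test_matches_enumeration_oracle_small_margins(self):
        rng = np.random.default_rng(123)
        for _ in range(300):
            t = rng.integers(0, 13, (2, 2))
            if t.sum(0).min() == 0 or t.sum(1).min() == 0:
                continue
            p = rf.fisher_exact_two_sided(self._table(t))
            assert p == pytest.approx(fisher_two_sided_oracle(t), abs=1e-12)
            assert 0.0 <= p <= 1.0

    def test_invariance_under_transpose_and_swaps(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            t = rng.integers(1, 15, (2, 2))
            p = rf.fisher_exact_two_sided(self._table(t))
            assert rf.fisher_exact_two_sided(self._table(t.T)) == \
                pytest.approx(p, abs=1e-12)
            assert rf.fisher_exact_two_sided(self._table(t[::-1, ::-1])) == \
                pytest.approx(p, abs=1e-12)

    def test_non_2x2_rejected(self):
        t = rf.ContingencyTable(np.ones((3, 2), int), ("a", "b", "c"),
                                ("x", "y"))
        with pytest.raises(ResiflexError, match="2x2"):
            rf.fisher_exact_two_sided(t)


class TestLoadAndValidate:
    def test_round_trip_through_csv(self, cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        cohort.to_csv(path, index=False)
        back = rf.load_cohort(path)
        assert len(back) == 68
        assert back["t790m"].tolist() == cohort["t790m"].tolist()

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(CohortValidationError):
            rf.load_cohort(path)

    def test_age_monotonicity_violation(self, cohort, tmp_path):
        bad = cohort.copy()
        bad.loc[0, "age_65"] = False
        bad.loc[0, "age_70"] = True
        path = tmp_path / "bad.csv"
        bad.to_csv(path, index=False)
        with pytest.raises(CohortValidationError, match="monotone"):
            rf.load_cohort(path)

    def test_unknown_level_names_row_and_column(self, cohort, tmp_path):
        bad = cohort.copy()
        bad.loc[3, "initial_egfr_mutation"] = "exon20_insertion"
        path = tmp_path / "bad.csv"
        bad.to_csv(path, index=False)
        with pytest.raises(CohortValidationError,
                           match="row 3.*initial_egfr_mutation"):
            rf.load_cohort(path)


class TestRankers:
    def test_perfect_predictor_tops_information_measures(self, cohort):
        df = cohort.copy()
        df["oracle_attr"] = df["t790m"]
        attrs = list(ATTRIBUTES) + ["oracle_attr"]
        h_outcome = -(27 / 68) * np.log2(27 / 68) - (41 / 68) * np.log2(41 / 68)
        ig = rf.rank_attributes(df, "info_gain", attributes=attrs)
        assert ig.top == "oracle_attr"
        assert dict(ig.ranking)["oracle_attr"] == pytest.approx(h_outcome)
        su = rf.rank_attributes(df, "symmetrical_uncertainty", attributes=attrs)
        assert su.top == "oracle_attr"
        assert dict(su.ranking)["oracle_attr"] == pytest.approx(1.0)

    def test_independent_attribute_scores_vanish(self):
        rng = np.random.default_rng(31)
        n = 5000
        df = pd.DataFrame({
            "noise": rng.random(n) < 0.5,
            "t790m": rng.random(n) < 0.4,
        })
        a, y = df["noise"].astype(str).to_numpy(), df["t790m"].astype(str).to_numpy()
        assert score_info_gain(a, y) < 5e-3
        assert score_symmetrical_uncertainty(a, y) < 5e-3
        assert score_chi2(a, y) < 7.0  # chi2_1 well inside its null range

    def test_exactly_independent_table_gives_zero_chi2(self):
        # counts = outer product of margins: 20x30 over levels
        a = np.repeat(["x", "y"], [30, 30])
        y = np.tile(np.repeat(["p", "n"], [10, 20]), 2)
        assert score_chi2(a, y) == pytest.approx(0.0, abs=1e-12)
        assert score_info_gain(a, y) == pytest.approx(0.0, abs=1e-12)

    def test_constant_attribute_scores_zero_not_error(self, cohort):
        df = cohort.copy()
        df["constant"] = True
        ranking = rf.rank_attributes(df, "correlation",
                                     attributes=list(ATTRIBUTES) + ["constant"])
        assert dict(ranking.ranking)["constant"] == 0.0

    def test_dominant_effect_ranks_first_under_all_evaluators(self):
        recipe = rf.CohortRecipe(n_patients=2000, seed=17,
                                 effects={"bone_met": 10.0})
        df = rf.generate_cohort(recipe)
        for ev in ("chi2", "info_gain", "symmetrical_uncertainty",
                   "correlation", "relieff"):
            ranking = rf.rank_attributes(df, ev, seed=5)
            assert ranking.top == "bone_met", ev

    def test_relieff_sampling_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        mat = rng.integers(0, 3, (60, 4)).astype(str)
        y = rng.integers(0, 2, 60).astype(str)
        w1 = score_relieff(mat, y, sample_size=20, seed=4)
        w2 = score_relieff(mat, y, sample_size=20, seed=4)
        w3 = score_relieff(mat, y, sample_size=20, seed=5)
        assert np.array_equal(w1, w2)
        assert not np.array_equal(w1, w3)

    def test_outcome_must_have_both_levels(self, cohort):
        df = cohort.copy()
        df["t790m"] = True
        with pytest.raises(ResiflexError, match="both levels"):
            rf.rank_attributes(df, "info_gain")
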