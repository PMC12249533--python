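"""AAE reports, the between-environment AAD matrix, and the two-way ANOVA.

statsmodels' anova_lm (typ=1) is the independent oracle for the sequential
sums of squares; textbook balanced-design formulas back the hand cases.
"""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import statsmodels.formula.api as smf

import pyraheight as ph
from pyraheight.errors import DegenerateInputError
from pyraheight.synthetic_data import EMPTY_TRUTH, expected_anova_percents

from conftest import locus_set, single_env_phenotypes, toy_genotypes, toy_phenotypes


def flat_model(intercept, genotypes):
    m0 = genotypes.marker_ids[0]
    return ph.HeightModel(
        slope=0.0, intercept=float(intercept), f_statistic=0.0, p_value=1.0,
        locus_set=locus_set((m0, genotypes.allele_catalog(m0)[0])),
    )


class TestAverageAbsoluteError:
    def two_line_setup(self):
        g = toy_genotypes({"MK": ["95", "100"]}, line_ids=["L1", "L2"])
        phen = single_env_phenotypes({"L1": 100.0, "L2": 130.0})
        model = ph.HeightModel(
            slope=2.5, intercept=115.0, f_statistic=1.0, p_value=0.5,
            locus_set=locus_set(("MK", "95")),
        )
        return g, phen, model

    def test_hand_arithmetic_two_lines(self):
        """P = (120, 110), R = (100, 130) -> AAE = (20 + 20)/2 = 20; the
        statistic is the mean of |P - R|, never the signed mean."""
        g, phen, model = self.two_line_setup()
        report = ph.average_absolute_error(model, g, phen)
        assert report.per_line.loc["L1", "predicted"] == pytest.approx(120.0)
        assert report.per_line.loc["L2", "predicted"] == pytest.approx(110.0)
        assert report.aae == pytest.approx(20.0)
        assert report.n == 2
        # the signed errors cancel; the absolute ones must not
        assert report.predicted_mean - report.real_mean == pytest.approx(0.0)

    def test_perfect_prediction_gives_zero(self):
        g = toy_genotypes({"MK": ["95", "100"]})
        phen = single_env_phenotypes({"L1": 120.0, "L2": 110.0})
        model = ph.HeightModel(2.5, 115.0, 1.0, 0.5, locus_set(("MK", "95")))
        assert ph.average_absolute_error(model, g, phen).aae == pytest.approx(0.0)

    def test_line_order_invariance(self, fixture_bundle):
        g, t = fixture_bundle.genotypes, fixture_bundle.phenotypes
        model = flat_model(118.0, g)
        a = ph.average_absolute_error(model, g, t).aae
        rev = ph.GenotypeMatrix(
            list(reversed(g.line_ids)),
            g.marker_ids,
            g.calls[::-1].copy(),
            g.marker_map,
        )
        assert ph.average_absolute_error(model, rev, t).aae == pytest.approx(a)

    def test_mean_gap_never_exceeds_aae(self, fixture_bundle):
        """|mean(P) - mean(R)| <= AAE for every report (Jensen bound)."""
        g, t = fixture_bundle.genotypes, fixture_bundle.phenotypes
        for intercept in (90.0, 115.0, 130.0):
            rep = ph.average_absolute_error(flat_model(intercept, g), g, t)
            assert abs(rep.predicted_mean - rep.real_mean) <= rep.aae + 1e-12

    def test_empty_validation_set_rejected(self):
        g, phen, model = self.two_line_setup()
        other = single_env_phenotypes({"Z9": 100.0})
        with pytest.raises(ph.ValidationError):
            ph.average_absolute_error(model, g, other)


class TestPairwiseAad:
    def three_env_toy(self):
        # line means: E1 = (100, 110), E2 = (104, 112), E3 = (100, 120)
        return toy_phenotypes(
            {
                ("L1", "E1"): [100.0], ("L2", "E1"): [110.0],
                ("L1", "E2"): [104.0], ("L2", "E2"): [112.0],
                ("L1", "E3"): [100.0], ("L2", "E3"): [120.0],
            }
        )

    def test_hand_computed_matrix(self):
        """AAD(E1,E2) = (|100-104| + |110-112|)/2 = 3, etc."""
        mat = ph.pairwise_environment_aad(self.three_env_toy())
        assert mat.loc["E1", "E2"] == pytest.approx(3.0)
        assert mat.loc["E1", "E3"] == pytest.approx(5.0)   # (0 + 10)/2
        assert mat.loc["E2", "E3"] == pytest.approx(6.0)   # (4 + 8)/2
        assert np.isnan(np.diag(mat)).all()
        pd.testing.assert_frame_equal(mat, mat.T)

    def test_duplicate_environment_gives_zero(self):
        phen = toy_phenotypes(
            {("L1", "A"): [100.0], ("L1", "B"): [100.0], ("L2", "A"): [110.0],
             ("L2", "B"): [110.0]}
        )
        assert ph.pairwise_environment_aad(phen).loc["A", "B"] == 0.0

    def test_disjoint_pair_is_flagged_unavailable(self):
        phen = toy_phenotypes({("L1", "A"): [100.0], ("L2", "B"): [110.0]})
        with pytest.warns(UserWarning, match="share no lines"):
            mat = ph.pairwise_environment_aad(phen)
        assert np.isnan(mat.loc["A", "B"])

    def test_band_is_matrix_extremes(self):
        band = ph.natural_variation_band(self.three_env_toy())
        assert band == (pytest.approx(3.0), pytest.approx(6.0))
        assert band[0] <= band[1]

    def test_single_environment_rejected(self):
        with pytest.raises(DegenerateInputError):
            ph.natural_variation_band(toy_phenotypes({("L1", "A"): [100.0]}))


class TestTwoWayAnova:
    def balanced_2x2(self):
        # cell means chosen by hand: G x E table [[100, 110], [120, 150]]
        cells = {("g1", "e1"): 100.0, ("g1", "e2"): 110.0,
                 ("g2", "e1"): 120.0, ("g2", "e2"): 150.0}
        heights = {}
        for (g, e), mu in cells.items():
            heights[(g, e)] = [mu - 1.0, mu + 1.0]  # 2 reps, within-cell var 2
        return toy_phenotypes(heights)

    def test_textbook_formulas_on_balanced_2x2(self):
        """SS match re*sum(g-means - grand)^2 and friends; error SS is the
        within-cell spread."""
        table = ph.two_way_anova(self.balanced_2x2()).table
        grand = 120.0
        ss_g = 2 * 2 * ((105 - grand) ** 2 + (135 - grand) ** 2)   # 1800
        ss_e = 2 * 2 * ((110 - grand) ** 2 + (130 - grand) ** 2)   # 800
        cell = np.array([[100, 110], [120, 150]], dtype=float)
        inter = cell - cell.mean(1, keepdims=True) - cell.mean(0, keepdims=True) + grand
        ss_i = 2 * np.sum(inter**2)                                 # 200
        assert table.loc["genotype", "sum_sq"] == pytest.approx(ss_g)
        assert table.loc["environment", "sum_sq"] == pytest.approx(ss_e)
        assert table.loc["interaction", "sum_sq"] == pytest.approx(ss_i)
        assert table.loc["error", "sum_sq"] == pytest.approx(8.0)
        assert list(table["df"]) == [1, 1, 1, 4]
        assert table.loc["genotype", "percent"] == pytest.approx(
            100 * ss_g / (ss_g + ss_e + ss_i)
        )

    def test_ss_conservation(self, fixture_bundle):
        """Corrected total SS = G + E + GxE + error to 1e-8 relative."""
        t = fixture_bundle.phenotypes
        table = ph.two_way_anova(t).table
        y = t.data["height"].to_numpy()
        total = float(((y - y.mean()) ** 2).sum())
        assert table["sum_sq"].sum() == pytest.approx(total, rel=1e-8)

    def test_balanced_order_swap_leaves_type1_ss_unchanged(self, fixture_bundle):
        t = fixture_bundle.phenotypes
        a = ph.two_way_anova(t, order=("genotype", "environment")).table
        b = ph.two_way_anova(t, order=("environment", "genotype")).table
        for src in ("genotype", "environment", "interaction", "error"):
            assert a.loc[src, "sum_sq"] == pytest.approx(b.loc[src, "sum_sq"], rel=1e-8)

    def test_unbalanced_sequential_ss_match_statsmodels(self):
        """Type I SS on an unbalanced layout agree with anova_lm(typ=1)."""
        rng = np.random.default_rng(17)
        rows = []
        for g in ("g1", "g2", "g3"):
            for e in ("e1", "e2"):
                for r in range(int(rng.integers(2, 5))):
                    rows.append({"line_id": g, "environment_id": e, "replicate": r + 1,
                                 "height": float(rng.normal(120, 10))})
        phen = ph.PhenotypeTable(pd.DataFrame(rows))
        table = ph.two_way_anova(phen).table
        fit = smf.ols(
            "height ~ C(line_id) + C(environment_id) + C(line_id):C(environment_id)",
            data=phen.data,
        ).fit()
        oracle = sm.stats.anova_lm(fit, typ=1)
        assert table.loc["genotype", "sum_sq"] == pytest.approx(
            oracle.loc["C(line_id)", "sum_sq"], rel=1e-8
        )
        assert table.loc["environment", "sum_sq"] == pytest.approx(
            oracle.loc["C(environment_id)", "sum_sq"], rel=1e-8
        )
        assert table.loc["interaction", "sum_sq"] == pytest.approx(
            oracle.loc["C(line_id):C(environment_id)", "sum_sq"], rel=1e-8
        )
        assert table.loc["error", "sum_sq"] == pytest.approx(
            oracle.loc["Residual", "sum_sq"], rel=1e-8
        )
        assert table.loc["genotype", "F"] == pytest.approx(
            oracle.loc["C(line_id)", "F"], rel=1e-8
        )

    def test_constant_heights_report_zero_percents_with_warning(self):
        phen = toy_phenotypes(
            {(g, e): [100.0, 100.0] for g in ("g1", "g2") for e in ("e1", "e2")}
        )
        with pytest.warns(UserWarning, match="zero"):
            table = ph.two_way_anova(phen)
        assert all(v == 0.0 for v in table.percents.values())

    def test_no_replication_rejected(self):
        phen = toy_phenotypes(
            {(g, e): [100.0 + hash((g, e)) % 7] for g in ("g1", "g2") for e in ("e1", "e2")}
        )
        with pytest.raises(DegenerateInputError, match="replication"):
            ph.two_way_anova(phen)

    def test_gxe_percent_grows_with_configured_gxe_variance(self, small_panel):
        """Doubling var_gxe raises the recovered interaction percent
        (seed-averaged 3-point grid)."""
        g, _ = small_panel
        recovered = []
        for var_gxe in (10.0, 40.0, 160.0):
            vals = []
            for seed in range(6):
                env = ph.EnvConfig(n_environments=3, n_replicates_per_line=2,
                                   var_genotype=50.0, var_environment=5.0,
                                   var_gxe=var_gxe, var_residual=5.0)
                phen = ph.simulate_phenotypes(g, EMPTY_TRUTH, env, seed=500 + seed)
                vals.append(ph.two_way_anova(phen).percents["interaction"])
            recovered.append(np.mean(vals))
        assert recovered[0] < recovered[1] < recovered[2]

    def test_round_trip_recovers_expected_percents(self, small_panel):
        """Generator -> ANOVA round trip: percents land near the expected-SS
        identity values (compact version of the study-scale check)."""
        g, _ = small_panel
        env = ph.EnvConfig(n_environments=3, n_replicates_per_line=2,
                           var_genotype=100.0, var_environment=8.0,
                           var_gxe=30.0, var_residual=10.0)
        expected = expected_anova_percents(env, g.n_lines)
        acc = {"genotype": [], "environment": [], "interaction": []}
        for seed in range(10):
            phen = ph.simulate_phenotypes(g, EMPTY_TRUTH, env, seed=900 + seed)
            pct = ph.two_way_anova(phen).percents
            for k in acc:
                acc[k].append(pct[k])
        for k in acc:
            assert np.mean(acc[k]) == pytest.approx(expected[k], abs=5.0)
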