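import math

import numpy as np
import pandas as pd
import pytest

from crosspredict.crosspred import CrossPrediction, CrossRanking
from crosspredict.trial import (
    FieldTrialTable,
    TrialAnalysis,
    anderson_darling_normal,
    family_observations,
    fit_trial_model,
    predicted_phenotype_distribution,
    prediction_correlations,
    ranking_overlap,
    read_families,
    read_trial,
    validate_families,
    variance_confidence_interval,
    write_families,
    write_trial,
)


def _balanced_trial(rng, n_entries=60, n_loc=4, n_blocks=4,
                    s_L=4.0, s_LB=2.0, s_e=1.0, gv=None):
    entries = [f"G{i:03d}" for i in range(n_entries)]
    if gv is None:
        gv = rng.normal(50.0, 3.0, n_entries)
    per_block = n_entries // n_blocks
    rows = []
    for li in range(n_loc):
        le = rng.normal(0, math.sqrt(s_L))
        be = rng.normal(0, math.sqrt(s_LB), n_blocks)
        perm = rng.permutation(n_entries)
        for k, ei in enumerate(perm):
            b = min(k // per_block, n_blocks - 1)
            rows.append(
                (entries[ei], f"L{li}", f"B{b}",
                 gv[ei] + le + be[b] + rng.normal(0, math.sqrt(s_e)))
            )
    return (
        FieldTrialTable(pd.DataFrame(rows, columns=["entry", "location", "block", "value"])),
        dict(zip(entries, gv)),
    )


class TestFieldTrialTable:
    def test_duplicate_plot_rejected(self):
        df = pd.DataFrame(
            {"entry": ["a", "a"], "location": ["L", "L"], "block": ["B", "B"],
             "value": [1.0, 2.0]}
        )
        with pytest.raises(ValueError, match="duplicate"):
            FieldTrialTable(df)

    def test_round_trip(self, rng, tmp_path):
        t, _ = _balanced_trial(rng, n_entries=8, n_loc=2, n_blocks=2)
        path = tmp_path / "trial.tsv"
        write_trial(t, path, header="x")
        back = read_trial(path)
        pd.testing.assert_frame_equal(back.table, t.table)


class TestTrialModel:
    def test_degenerate_single_plot_design(self):
        """One location, one block, zero noise: adjusted means are the plot
        values and the masking variance collapses to ~0."""
        rows = [(f"G{i}", "L1", "B1", float(i)) for i in range(6)]
        t = FieldTrialTable(
            pd.DataFrame(rows, columns=["entry", "location", "block", "value"])
        )
        ta = fit_trial_model(t)
        np.testing.assert_allclose(ta.adjusted_means, np.arange(6.0), atol=1e-8)
        assert ta.masking_variance < 1e-4

    def test_translation_equivariance(self, rng):
        t, _ = _balanced_trial(rng, n_entries=20, n_loc=3, n_blocks=2)
        ta = fit_trial_model(t)
        shifted = FieldTrialTable(t.table.assign(value=t.table["value"] + 100.0))
        ta2 = fit_trial_model(shifted)
        # agreement is limited by the REML optimizer's convergence tolerance
        np.testing.assert_allclose(ta2.adjusted_means, ta.adjusted_means + 100.0, atol=1e-5)
        np.testing.assert_allclose(ta2.standard_errors, ta.standard_errors, atol=1e-4)
        assert ta2.masking_variance == pytest.approx(ta.masking_variance, rel=1e-3)

    def test_matches_statsmodels_mixedlm(self, rng):
        """Independent oracle: homoscedastic REML fit agrees with
        statsmodels MixedLM (variance components and adjusted means)."""
        import statsmodels.formula.api as smf

        t, _ = _balanced_trial(rng, n_entries=40, n_loc=4, n_blocks=4)
        ta = fit_trial_model(t)
        df = t.table
        fit = smf.mixedlm(
            "value ~ 0 + C(entry)", df, groups=df["location"], re_formula="1",
            vc_formula={"blk": "0 + C(block)"},
        ).fit(reml=True)
        assert ta.variance_components["sigma2_location"] == pytest.approx(
            float(fit.cov_re.iloc[0, 0]), rel=0.02, abs=0.02
        )
        assert ta.variance_components["sigma2_location_block"] == pytest.approx(
            float(fit.vcomp[0]), rel=0.02, abs=0.02
        )
        assert ta.variance_components["sigma2_error"] == pytest.approx(
            float(fit.scale), rel=0.02
        )
        np.testing.assert_allclose(
            ta.adjusted_means, fit.fe_params.to_numpy(), atol=1e-3
        )

    def test_heteroscedastic_flag_reports_per_location(self, rng):
        t, _ = _balanced_trial(rng, n_entries=30, n_loc=3, n_blocks=3)
        ta = fit_trial_model(t, heteroscedastic=True)
        err = ta.variance_components["sigma2_error"]
        assert set(err) == set(t.locations)
        assert all(v > 0 for v in err.values())

    def test_missing_entry_not_estimable(self, rng):
        t, _ = _balanced_trial(rng, n_entries=10, n_loc=2, n_blocks=2)
        with pytest.raises(ValueError, match="GHOST"):
            fit_trial_model(t, entries=t.entries + ["GHOST"])

    def test_augmented_design_recovers_order(self, rng):
        """Unreplicated entries + replicated checks: adjusted means track the
        simulated genotypic values."""
        gv = {f"T{i:02d}": float(v) for i, v in enumerate(rng.normal(50, 5, 40))}
        gv.update({f"C{i}": 50.0 + i for i in range(3)})
        rows = []
        for li in range(5):
            le = rng.normal(0, 2.0)
            be = rng.normal(0, 1.0, 4)
            blocks = rng.integers(0, 4, size=40)
            for (e, v), b in zip(list(gv.items())[:40], blocks):
                rows.append((e, f"L{li}", f"B{b}", v + le + be[b] + rng.normal(0, 1.5)))
            for c in ("C0", "C1", "C2"):
                for b in range(4):
                    rows.append((c, f"L{li}", f"B{b}", gv[c] + le + be[b] + rng.normal(0, 1.5)))
        t = FieldTrialTable(pd.DataFrame(rows, columns=["entry", "location", "block", "value"]))
        ta = fit_trial_model(t)
        est = np.array([ta.mean_of(e) for e in gv])
        truth = np.array(list(gv.values()))
        assert np.corrcoef(est, truth)[0, 1] > 0.95


class TestPhenotypeDistribution:
    def test_widening_by_masking_variance(self):
        cp = CrossPrediction("A", "B", "DH_from_F1", 90.0, 15.20, 10)
        dist = predicted_phenotype_distribution(cp, 33.41)
        assert dist.variance == pytest.approx(48.61)
        assert dist.variance > 15.20 and dist.variance > 33.41

    def test_zero_genetic_variance(self):
        cp = CrossPrediction("A", "B", "DH_from_F1", 90.0, 0.0, 0)
        assert predicted_phenotype_distribution(cp, 2.5).variance == 2.5

    def test_degenerate_distribution_rejected(self):
        cp = CrossPrediction("A", "B", "DH_from_F1", 90.0, 0.0, 0)
        with pytest.raises(ValueError, match="degenerate"):
            predicted_phenotype_distribution(cp, 0.0)


class TestAndersonDarling:
    def test_single_point_at_mean(self):
        res = anderson_darling_normal(np.array([3.0]), 3.0, 4.0)
        assert res.A2 == pytest.approx(2 * math.log(2) - 1, abs=1e-10)

    def test_gross_misfit(self):
        x = np.full(20, 10.0) + np.linspace(0, 0.1, 20)
        with pytest.warns(RuntimeWarning):
            res = anderson_darling_normal(x, 0.0, 1.0)
        assert res.p_value < 1e-6

    def test_affine_invariance(self, rng):
        x = rng.normal(5.0, 2.0, 25)
        base = anderson_darling_normal(x, 5.0, 4.0)
        scaled = anderson_darling_normal(3.0 * x - 7.0, 3.0 * 5.0 - 7.0, 9.0 * 4.0)
        assert scaled.A2 == pytest.approx(base.A2, rel=1e-12)

    def test_p_monotone_in_a2(self):
        from crosspredict.trial import _ad_cdf

        grid = np.linspace(0.05, 8.0, 50)
        cdf = [_ad_cdf(15, z) for z in grid]
        assert all(a <= b + 1e-12 for a, b in zip(cdf, cdf[1:]))

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            anderson_darling_normal(np.array([1.0]), 0.0, 0.0)


class TestVarianceCI:
    def test_chi_square_quantile_form(self):
        from scipy import stats

        lower, upper = variance_confidence_interval(10.0, 5)
        assert lower == pytest.approx(40.0 / stats.chi2.ppf(0.975, 4))
        assert upper == pytest.approx(40.0 / stats.chi2.ppf(0.025, 4))

    def test_zero_variance(self):
        assert variance_confidence_interval(0.0, 10) == (0.0, 0.0)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            variance_confidence_interval(1.0, 1)


def _ta(values: dict[str, float]) -> TrialAnalysis:
    ids = list(values)
    return TrialAnalysis(
        ids, np.array([values[e] for e in ids]), np.ones(len(ids)),
        {"sigma2_location": 0.0, "sigma2_location_block": 0.0, "sigma2_error": 1.0},
        0.0, True,
    )


class TestFamilyObservations:
    def test_summary_arithmetic(self):
        ta = _ta({"e1": 1.0, "e2": 2.0, "e3": 3.0, "solo": 9.0})
        obs = family_observations(ta, {"F1": ["e1", "e2", "e3"], "F2": ["solo"]})
        f1 = next(o for o in obs if o.cross_id == "F1")
        f2 = next(o for o in obs if o.cross_id == "F2")
        assert (f1.observed_mean, f1.observed_variance, f1.best_line_value) == (2.0, 1.0, 3.0)
        assert f2.n == 1 and f2.observed_variance is None and f2.best_line_value == 9.0

    def test_constant_family_zero_variance(self):
        ta = _ta({"a": 4.0, "b": 4.0})
        (obs,) = family_observations(ta, {"F": ["a", "b"]})
        assert obs.observed_variance == 0.0

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError, match="no members"):
            family_observations(_ta({"a": 1.0}), {"F": []})


class TestPredictionCorrelations:
    def _observations(self, means, variances):
        """Families P<i>xQ whose member values realise the given moments."""
        ta = _ta(
            {f"e{i}{j}": m + d for i, (m, v) in enumerate(zip(means, variances))
             for j, d in enumerate((-np.sqrt(v), 0.0, np.sqrt(v)))}
        )
        fam = {f"P{i}xQ": [f"e{i}0", f"e{i}1", f"e{i}2"] for i in range(len(means))}
        return family_observations(ta, fam)

    @staticmethod
    def _matching_preds(obs, mean_sign=1.0):
        return [
            CrossPrediction(o.cross_id.partition("x")[0], "Q", "DH_from_F1",
                            mean_sign * o.observed_mean, o.observed_variance, 1)
            for o in obs
        ]

    def test_perfect_agreement(self):
        obs = self._observations([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        r_m, r_v = prediction_correlations(obs, self._matching_preds(obs))
        assert r_m == pytest.approx(1.0)
        assert r_v == pytest.approx(1.0)

    def test_anticorrelated_means(self):
        obs = self._observations([1.0, 2.0, 3.0], [1.0, 1.5, 2.0])
        r_m, _ = prediction_correlations(obs, self._matching_preds(obs, mean_sign=-1.0))
        assert r_m == pytest.approx(-1.0)

    def test_too_few_pairs(self):
        obs = self._observations([1.0, 2.0], [1.0, 1.0])
        with pytest.raises(ValueError, match=">= 3"):
            prediction_correlations(obs, self._matching_preds(obs))


class TestRankingOverlap:
    def _ranking(self, ids):
        return CrossRanking([(c, float(-i)) for i, c in enumerate(ids)], "test")

    def test_identical_full_overlap(self):
        ids = [f"c{i}" for i in range(14)]
        assert ranking_overlap(self._ranking(ids), self._ranking(ids)) == (7, 7, 1.0)

    def test_reversed_zero_overlap(self):
        ids = [f"c{i}" for i in range(14)]
        assert ranking_overlap(self._ranking(ids), self._ranking(ids[::-1])) == (7, 0, 0.0)

    def test_random_rankings_hypergeometric_mean(self, rng):
        """Independent rankings of 14 crosses share on average k^2/m = 3.5
        of their top halves."""
        ids = [f"c{i}" for i in range(14)]
        matches = []
        for _ in range(4000):
            a = list(ids)
            b = list(ids)
            rng.shuffle(a)
            rng.shuffle(b)
            matches.append(ranking_overlap(self._ranking(a), self._ranking(b))[1])
        assert np.mean(matches) == pytest.approx(3.5, abs=0.1)

    def test_set_mismatch(self):
        with pytest.raises(ValueError, match="different"):
            ranking_overlap(self._ranking(["a", "b"]), self._ranking(["a", "c"]))


def test_families_round_trip(tmp_path):
    fam = {"F1": ["a", "b"], "F2": ["c"]}
    path = tmp_path / "families.tsv"
    write_families(fam, path)
    assert read_families(path) == fam
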