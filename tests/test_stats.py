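"""Mixed ANCOVA, the 3 dB rule, survey ANOVA and CCA."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg

from reefpam.stats import (
    apply_3db_rule,
    fit_ancova,
    fit_survey_anova,
    run_cca,
    summarize_group_differences,
)

LOCATIONS = ["West", "Northwest", "North", "East"]


def make_feature_table(
    rng,
    n_days=6,
    year_effect=0.0,
    protection_effect=0.0,
    loc_sd=1.0,
    noise_sd=1.0,
    center_locations=False,
):
    rows = []
    loc_eff = {l: rng.normal(0, loc_sd) for l in LOCATIONS}
    for loc in LOCATIONS:
        for prot in ("MPA", "nMPA"):
            for year in ("2015", "2021"):
                for d in range(n_days):
                    y = (
                        60.0
                        + loc_eff[loc]
                        + year_effect * (year == "2021")
                        + protection_effect * (prot == "MPA")
                        + rng.normal(0, noise_sd)
                    )
                    rows.append(
                        dict(
                            site=f"{prot}{loc}",
                            protection=prot,
                            year=year,
                            location=loc,
                            moon_phase=rng.random(),
                            psd_fpeak_db=y,
                        )
                    )
    tab = pd.DataFrame(rows)
    if center_locations:
        tab["psd_fpeak_db"] -= tab.groupby("location")["psd_fpeak_db"].transform("mean") - 60.0
    return tab


class TestFitAncova:
    def test_detects_injected_year_effect(self, rng):
        tab = make_feature_table(rng, year_effect=6.0, noise_sd=2.0)
        res = fit_ancova(tab, "psd_fpeak_db")
        assert res.terms["year"].p < 1e-3
        assert res.terms["year"].chi2 > 0
        assert set(res.terms) == {"protection", "year", "protection:year", "moon_phase"}

    def test_power_for_six_db_effect(self, rng):
        # 8 sites x 14 days, 2 dB noise: the year term is essentially always seen
        hits = 0
        for _ in range(20):
            tab = make_feature_table(rng, n_days=14, year_effect=6.0, noise_sd=2.0)
            if fit_ancova(tab, "psd_fpeak_db").terms["year"].p < 0.001:
                hits += 1
        assert hits == 20

    def test_boundary_fit_matches_ols_type2(self, rng):
        # response centered within locations: the REML optimum is at the
        # zero-variance boundary, where the mixed Wald tests must agree with
        # an ordinary least-squares type-II ANCOVA
        import statsmodels.formula.api as smf

        tab = make_feature_table(rng, loc_sd=0.0, center_locations=True)
        res = fit_ancova(tab, "psd_fpeak_db")
        assert res.location_variance == pytest.approx(0.0, abs=1e-8)

        terms = ["C(protection)", "C(year)", "C(protection):C(year)", "moon_phase"]
        names = ["protection", "year", "protection:year", "moon_phase"]
        for nm, t in zip(names, terms):
            keep = [
                u for u in terms if u == t or not (set(u.split(":")) > set(t.split(":")))
            ]
            m = smf.ols("psd_fpeak_db ~ " + " + ".join(keep), tab).fit()
            di = m.model.data.design_info
            cols = None
            for tn, sl in di.term_name_slices.items():
                if tn == t:
                    cols = list(range(*sl.indices(len(di.column_names))))
            b = m.params.values[cols]
            V = m.cov_params().values[np.ix_(cols, cols)]
            chi2_ols = float(b @ np.linalg.inv(V) @ b)
            assert res.terms[nm].chi2 == pytest.approx(chi2_ols, rel=1e-3)

    def test_site_order_permutation_invariant(self, rng):
        tab = make_feature_table(rng, year_effect=3.0)
        res1 = fit_ancova(tab, "psd_fpeak_db")
        shuffled = tab.sample(frac=1.0, random_state=0).reset_index(drop=True)
        res2 = fit_ancova(shuffled, "psd_fpeak_db")
        for k in res1.terms:
            assert res1.terms[k].chi2 == pytest.approx(res2.terms[k].chi2, rel=1e-6)

    def test_requires_two_locations(self, rng):
        tab = make_feature_table(rng)
        tab = tab[tab.location == "West"]
        with pytest.raises(ValueError):
            fit_ancova(tab, "psd_fpeak_db")


class TestSurveyAnova:
    def test_identical_groups_give_zero_chi2(self):
        sv = pd.DataFrame(
            dict(
                site=[f"s{i}" for i in range(8)],
                protection=["MPA"] * 4 + ["nMPA"] * 4,
                location=["West", "North", "East", "Northwest"] * 2,
                abundance=[10.0, 12.0, 14.0, 16.0] * 2,
            )
        )
        t = fit_survey_anova(sv, "abundance")
        assert t.chi2 < 1e-10 or t.p > 0.999

    def test_large_richness_effect_detected(self, rng):
        rows = []
        for i in range(24):
            prot = "MPA" if i % 2 == 0 else "nMPA"
            rows.append(
                dict(
                    site=f"s{i}",
                    protection=prot,
                    location=LOCATIONS[(i // 2) % 4],
                    richness=20 + 10 * (prot == "MPA") + rng.normal(0, 2),
                )
            )
        t = fit_survey_anova(pd.DataFrame(rows), "richness")
        assert t.p < 0.01

    def test_missing_metric_rejected(self):
        sv = pd.DataFrame(dict(protection=["MPA", "nMPA"], location=["West", "West"]))
        with pytest.raises(KeyError):
            fit_survey_anova(sv, "biomass")


class Test3dbRule:
    @pytest.mark.parametrize(
        "diff,p,expected",
        [
            (4.07, 1e-5, "significant"),
            (2.88, 0.01, "non-significant"),
            (1.96, 0.01, "non-significant"),
            (3.41, 0.01, "significant"),
            (4.79, 1e-4, "significant"),
            (5.93, 1e-4, "significant"),
            (-3.13, 0.01, "significant"),  # magnitude rule: sign-free
            (3.83, 0.2, "non-significant"),  # loud but not statistically so
        ],
    )
    def test_reported_style_calls(self, diff, p, expected):
        assert apply_3db_rule(diff, p).verdict == expected

    def test_monotone_in_difference_and_p(self, rng):
        for _ in range(200):
            d, p = rng.uniform(0, 8), rng.uniform(0, 1)
            v = apply_3db_rule(d, p).verdict
            stronger = apply_3db_rule(d + rng.uniform(0, 3), p * rng.uniform(0, 1)).verdict
            if v == "significant":
                assert stronger == "significant"

    def test_margin_must_be_positive(self):
        with pytest.raises(ValueError):
            apply_3db_rule(5.0, 0.01, margin=0.0)


def brute_force_cca_eigenvalues(Y, X):
    """Independent oracle: explicit projection + symmetric eigenproblem."""
    Y = np.asarray(Y, float)
    X = np.asarray(X, float)
    P = Y / Y.sum()
    r, c = P.sum(1), P.sum(0)
    Q = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    Xc = X - r @ X
    Xw = np.sqrt(r)[:, None] * Xc
    H = Xw @ np.linalg.pinv(Xw.T @ Xw) @ Xw.T
    M = H @ Q
    ev = np.linalg.eigvalsh(M @ M.T)[::-1]
    return ev[ev > 1e-10]


class TestCca:
    def _fixture(self, rng, n_sites=8, n_taxa=10):
        Y = pd.DataFrame(
            rng.poisson(6, (n_sites, n_taxa)).astype(float) + 0.5,
            index=[f"s{i}" for i in range(n_sites)],
            columns=[f"t{j}" for j in range(n_taxa)],
        )
        X = pd.DataFrame(
            rng.normal(size=(n_sites, 3)), index=Y.index, columns=["x1", "x2", "x3"]
        )
        return Y, X

    def test_matches_bruteforce_eigenproblem(self, rng):
        for _ in range(5):
            Y, X = self._fixture(rng)
            res = run_cca(Y, X)
            oracle = brute_force_cca_eigenvalues(Y, X)
            np.testing.assert_allclose(res.eigenvalues, oracle, atol=1e-8)

    def test_matches_skbio_reference(self, rng):
        from skbio.stats.ordination import cca as skbio_cca

        Y, X = self._fixture(rng, n_sites=6, n_taxa=5)
        res = run_cca(Y, X)
        ref = skbio_cca(Y, X)
        np.testing.assert_allclose(
            res.eigenvalues, ref.eigvals.values[: len(res.eigenvalues)], atol=1e-8
        )

    def test_group_determined_composition_recovers_ca_axis(self, rng):
        # two site groups with identical within-group profiles: the group
        # indicator captures the entire first CA axis
        prof_a = np.array([5.0, 1.0, 1.0, 3.0])
        prof_b = np.array([1.0, 4.0, 2.0, 1.0])
        Y = pd.DataFrame(
            [prof_a * k for k in (1, 2, 3)] + [prof_b * k for k in (1, 2, 3)],
            index=[f"s{i}" for i in range(6)],
        )
        X = pd.DataFrame({"group": [1.0, 1, 1, 0, 0, 0]}, index=Y.index)
        res = run_cca(Y, X)
        # unconstrained CA of the same table
        P = Y.to_numpy() / Y.to_numpy().sum()
        r, c = P.sum(1), P.sum(0)
        Q = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        ca1 = linalg.svdvals(Q)[0] ** 2
        assert res.eigenvalues[0] == pytest.approx(ca1, abs=1e-8)

    def test_saturated_constraints_recover_total_inertia(self, rng):
        Y, _ = self._fixture(rng, n_sites=6, n_taxa=4)
        X = pd.get_dummies(pd.Series(Y.index, index=Y.index)).astype(float)
        with pytest.warns(UserWarning, match="aliased"):
            res = run_cca(Y, X)
        assert res.eigenvalues.sum() == pytest.approx(res.total_inertia, abs=1e-8)
        assert res.proportion_constrained == pytest.approx(1.0, abs=1e-8)

    def test_unrelated_constraints_explain_less_than_first_axis(self, rng):
        Y, _ = self._fixture(rng, n_sites=8, n_taxa=6)
        X = pd.DataFrame({"noise": rng.normal(size=8)}, index=Y.index)
        res = run_cca(Y, X)
        P = Y.to_numpy() / Y.to_numpy().sum()
        r, c = P.sum(1), P.sum(0)
        Q = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        ca_first_share = linalg.svdvals(Q)[0] ** 2 / (Q**2).sum()
        assert res.proportion_constrained < ca_first_share

    def test_site_scores_orthonormal_under_weights(self, rng):
        Y, X = self._fixture(rng)
        res = run_cca(Y, X)
        P = Y.to_numpy() / Y.to_numpy().sum()
        r = P.sum(1)
        S = res.site_scores.to_numpy()
        G = (S * r[:, None]).T @ S
        np.testing.assert_allclose(G, np.eye(S.shape[1]), atol=1e-6)

    def test_site_permutation_invariant_eigenvalues(self, rng):
        Y, X = self._fixture(rng)
        res1 = run_cca(Y, X)
        perm = rng.permutation(len(Y))
        res2 = run_cca(Y.iloc[perm], X.iloc[perm])
        np.testing.assert_allclose(res1.eigenvalues, res2.eigenvalues, atol=1e-10)

    def test_zero_rows_and_columns_dropped_with_warning(self, rng):
        Y, X = self._fixture(rng, n_sites=6, n_taxa=5)
        Y.iloc[2] = 0.0
        Y.iloc[:, 3] = 0.0
        with pytest.warns(UserWarning, match="all-zero"):
            res = run_cca(Y, X)
        assert res.dropped_sites == ["s2"]
        assert res.dropped_taxa == ["t3"]


class TestSummarizeGroupDifferences:
    def test_constant_groups(self):
        tab = pd.DataFrame(
            dict(
                site=["a"] * 4 + ["b"] * 4,
                year=["2015", "2015", "2021", "2021"] * 2,
                psd_fpeak_db=[60.0, 60.0, 64.0, 64.0] * 2,
            )
        )
        s = summarize_group_differences(tab, "psd_fpeak_db", "year")
        assert s.overall_difference == pytest.approx(4.0)
        assert np.allclose(s.cell_table["delta_audit_db"], 0.0)
        assert np.allclose(s.differences["difference_db"], 4.0)

    def test_delta_audit_nonnegative(self, rng):
        tab = pd.DataFrame(
            dict(
                site=rng.choice(["a", "b", "c"], 60),
                year=rng.choice(["2015", "2021"], 60),
                psd_fpeak_db=rng.uniform(40, 80, 60),
            )
        )
        s = summarize_group_differences(tab, "psd_fpeak_db", "year")
        assert (s.cell_table["delta_audit_db"] >= -1e-12).all()

    def test_needs_exactly_two_levels(self):
        tab = pd.DataFrame(dict(site=["a"], year=["2015"], psd_fpeak_db=[60.0]))
        with pytest.raises(ValueError):
            summarize_group_differences(tab, "psd_fpeak_db", "year")
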