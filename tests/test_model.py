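"""Conditional-logistic likelihood, fitting, stepwise selection, screening.

The likelihood is cross-checked against three independent routes: direct
enumeration of the within-stratum softmax, statsmodels' ConditionalLogit,
and coefficients from R's survival::clogit frozen at build time on a
bit-reproducible fixture.
"""

import numpy as np
import pandas as pd
import pytest

from fishssf.errors import DesignError, RankDeficiencyError
from fishssf.model import (DesignData, ModelSpec, backward_stepwise,
                           build_design, clogit_hessian, clogit_nll_grad,
                           correlation_screen, empty_model, fit_clogit,
                           model_concordance, retain_complex,
                           saturated_spec_for_fish, subset_design)
from fishssf.terms import saturated_term_labels


def design_from_arrays(X, strata, case, labels=None):
    order = np.argsort(strata, kind="stable")
    X, strata, case = X[order], np.asarray(strata)[order], np.asarray(case)[order]
    labels = labels or [f"x{j}" for j in range(X.shape[1])]
    return DesignData(X=X, column_labels=labels, column_terms=list(labels),
                      strata=strata, case=case.astype(bool),
                      group_sizes=np.bincount(strata))


def random_design(rng, n_strata=5, size=4, p=3):
    X = rng.normal(size=(n_strata * size, p))
    strata = np.repeat(np.arange(n_strata), size)
    case = np.zeros(n_strata * size, dtype=bool)
    for g in range(n_strata):
        case[g * size + rng.integers(size)] = True
    return design_from_arrays(X, strata, case)


def enumerate_nll(beta, X, strata, case):
    """Brute-force oracle: explicit softmax probability of each case."""
    total = 0.0
    for g in np.unique(strata):
        idx = np.flatnonzero(strata == g)
        scores = np.exp(X[idx] @ beta)
        p_case = scores[case[idx]].item() / scores.sum()
        total -= np.log(p_case)
    return total


class TestLikelihood:
    def test_null_nll_is_log_group_sizes(self):
        rng = np.random.default_rng(0)
        d = random_design(rng, n_strata=7, size=11, p=2)
        nll, grad = clogit_nll_grad(np.zeros(2), d)
        assert nll == pytest.approx(7 * np.log(11), rel=1e-12)

    def test_two_candidate_closed_form(self):
        # case-control difference 1 in one covariate, beta = ln 3:
        # P(case) = 3/(3+1) -> NLL = ln(4/3)
        X = np.array([[1.0], [0.0]])
        d = design_from_arrays(X, np.array([0, 0]), np.array([True, False]))
        nll, _ = clogit_nll_grad(np.array([np.log(3.0)]), d)
        assert nll == pytest.approx(np.log(4.0 / 3.0), rel=1e-12)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        for trial in range(10):
            d = random_design(rng, n_strata=3, size=3, p=3)
            beta = rng.normal(size=3)
            nll, _ = clogit_nll_grad(beta, d)
            oracle = enumerate_nll(beta, d.X, d.strata, d.case)
            assert abs(nll - oracle) < 1e-10

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        d = random_design(rng, n_strata=6, size=5, p=4)
        beta = rng.normal(size=4) * 0.5
        _, grad = clogit_nll_grad(beta, d)
        fd = np.zeros(4)
        h = 1e-6
        for j in range(4):
            e = np.zeros(4); e[j] = h
            fd[j] = (clogit_nll_grad(beta + e, d)[0]
                     - clogit_nll_grad(beta - e, d)[0]) / (2 * h)
        assert np.allclose(grad, fd, atol=1e-6)

    def test_hessian_matches_gradient_differences(self):
        rng = np.random.default_rng(3)
        d = random_design(rng, n_strata=5, size=4, p=3)
        beta = rng.normal(size=3) * 0.3
        H = clogit_hessian(beta, d)
        h = 1e-6
        for j in range(3):
            e = np.zeros(3); e[j] = h
            col = (clogit_nll_grad(beta + e, d)[1]
                   - clogit_nll_grad(beta - e, d)[1]) / (2 * h)
            assert np.allclose(H[:, j], col, atol=1e-5)

    def test_wrong_beta_length_rejected(self):
        d = random_design(np.random.default_rng(4))
        with pytest.raises(DesignError):
            clogit_nll_grad(np.zeros(99), d)


def r_oracle_fixture():
    """Bit-reproducible fixture fitted with survival::clogit at build time."""
    rng = np.random.default_rng(20180807)
    true_beta = np.array([0.8, -0.5, 0.3])
    X_all, strata, case = [], [], []
    for s in range(20):
        X = rng.normal(size=(6, 3))
        lp = X @ true_beta
        p = np.exp(lp - lp.max()); p /= p.sum()
        chosen = rng.choice(6, p=p)
        X_all.append(X)
        strata.extend([s] * 6)
        case.extend(j == chosen for j in range(6))
    return design_from_arrays(np.vstack(X_all), np.array(strata),
                              np.array(case))


class TestFitting:
    # frozen output of survival::clogit on r_oracle_fixture()
    R_COEF = np.array([1.1739359465568, -0.1766780066052, 0.0830429104411])
    R_SE = np.array([0.344927708193, 0.355384353873, 0.273770593798])
    R_LOGLIK = -28.0002407540
    R_CONCORDANCE = 0.68

    def test_matches_r_survival_clogit(self):
        d = r_oracle_fixture()
        m = fit_clogit(d)
        assert np.allclose(m.beta, self.R_COEF, atol=1e-6)
        assert np.allclose(m.se, self.R_SE, atol=1e-5)
        assert m.loglik == pytest.approx(self.R_LOGLIK, abs=1e-6)
        assert m.concordance == pytest.approx(self.R_CONCORDANCE, abs=1e-12)

    def test_matches_statsmodels_conditional_logit(self):
        from statsmodels.discrete.conditional_models import ConditionalLogit

        d = r_oracle_fixture()
        sm_fit = ConditionalLogit(d.case.astype(int), d.X,
                                  groups=d.strata).fit(disp=False)
        ours = fit_clogit(d)
        # statsmodels converges less tightly than the Newton fit here
        assert np.allclose(ours.beta, sm_fit.params, atol=5e-4)

    def test_optimum_gradient_is_tiny_and_aic_consistent(self):
        d = r_oracle_fixture()
        m = fit_clogit(d)
        _, grad = clogit_nll_grad(m.beta, d)
        assert np.linalg.norm(grad, np.inf) < 1e-6
        assert m.aic == pytest.approx(2 * 3 - 2 * m.loglik, rel=1e-12)

    def test_recovers_known_coefficients(self):
        rng = np.random.default_rng(6)
        true = np.array([0.6, 0.4])
        X_all, strata, case = [], [], []
        for s in range(500):
            X = rng.normal(size=(11, 2))
            lp = X @ true
            p = np.exp(lp - lp.max()); p /= p.sum()
            chosen = rng.choice(11, p=p)
            X_all.append(X); strata.extend([s] * 11)
            case.extend(j == chosen for j in range(11))
        d = design_from_arrays(np.vstack(X_all), np.array(strata), np.array(case))
        m = fit_clogit(d)
        assert np.all(np.abs(m.beta - true) < 3 * m.se)

    def test_null_calibration_of_wald_intervals(self):
        rng = np.random.default_rng(7)
        inside = 0
        reps = 200
        for _ in range(reps):
            d = random_design(rng, n_strata=50, size=5, p=1)
            m = fit_clogit(d)
            inside += bool(abs(m.beta[0]) < 3 * m.se[0])
        assert inside / reps >= 0.95

    def test_duplicated_column_raises_rank_error(self):
        rng = np.random.default_rng(8)
        d = random_design(rng, n_strata=5, size=4, p=2)
        X = np.column_stack([d.X, d.X[:, 0]])
        dd = DesignData(X=X, column_labels=["a", "b", "a_copy"],
                        column_terms=["a", "b", "a_copy"], strata=d.strata,
                        case=d.case, group_sizes=d.group_sizes)
        with pytest.raises(RankDeficiencyError) as err:
            fit_clogit(dd)
        assert "a_copy" in err.value.columns or "a" in err.value.columns

    def test_nesting_never_hurts_likelihood(self):
        rng = np.random.default_rng(9)
        d = random_design(rng, n_strata=40, size=5, p=3)
        full = fit_clogit(d)
        sub = fit_clogit(subset_design(d, ["x0", "x1"]), check_rank=False)
        assert full.loglik >= sub.loglik - 1e-9


class TestConcordance:
    def test_null_model_all_ties(self):
        d = random_design(np.random.default_rng(10), n_strata=6, size=11, p=2)
        m = fit_clogit(d, max_iter=0)
        assert model_concordance(m, d) == 0.5

    def test_perfect_ranking(self):
        X = np.zeros((22, 1))
        case = np.zeros(22, dtype=bool)
        for g in range(2):
            X[g * 11, 0] = 5.0
            case[g * 11] = True
        d = design_from_arrays(X, np.repeat([0, 1], 11), case)
        m = fit_clogit(d, max_iter=0)
        m.beta = np.array([1.0])
        assert model_concordance(m, d) == 1.0

    def test_hand_counted_example(self):
        # stratum 1: case beats 7, ties 1, loses 2; stratum 2: beats all 10
        s1 = np.r_[5.0, np.full(7, 1.0), 5.0, 8.0, 9.0]
        s2 = np.r_[5.0, np.full(10, 1.0)]
        X = np.r_[s1, s2][:, None]
        case = np.zeros(22, dtype=bool); case[0] = case[11] = True
        d = design_from_arrays(X, np.repeat([0, 1], 11), case)
        m = fit_clogit(d, max_iter=0)
        m.beta = np.array([1.0])
        assert model_concordance(m, d) == pytest.approx((7 + 0.5 + 10) / 20)


class TestStepwise:
    def test_retention_rule_boundary(self):
        # complex retained only when its AIC is at least delta lower
        assert retain_complex(100.0, 102.0, delta=2.0)          # exactly 2 lower
        assert retain_complex(100.0, 103.0, delta=2.0)
        assert not retain_complex(100.0, 101.9, delta=2.0)      # only 1.9 lower
        assert not retain_complex(100.0, 100.0, delta=2.0)

    @staticmethod
    def simulated_table(rng, n_strata=800, beta=(0.8, 0.6, 0.0, 0.0, 0.0)):
        beta = np.asarray(beta, dtype=float)
        p = len(beta)
        rows = []
        for s in range(n_strata):
            X = rng.normal(size=(11, p))
            lp = X @ beta
            pr = np.exp(lp - lp.max()); pr /= pr.sum()
            chosen = rng.choice(11, p=pr)
            for j in range(11):
                row = {"stratum": f"s{s:04d}", "case": j == chosen, "tod": "day"}
                row.update({f"c{i}": X[j, i] for i in range(p)})
                rows.append(row)
        df = pd.DataFrame(rows)
        return df

    def test_signal_terms_survive_and_noise_is_pruned(self):
        rng = np.random.default_rng(11)
        df = self.simulated_table(rng)
        # stand the generic columns in for standardized model columns
        df = df.rename(columns={
            "c0": "wv_end_z", "c1": "d_end_z", "c2": "svg_end_z",
            "c3": "diffvang_end_z", "c4": "diffsvgang_end_z"})
        spec = ModelSpec(terms=["WV (end)", "D (end)", "SVG (end)",
                                "DiffVang (end)", "DiffSVGang (end)"])
        model, history = backward_stepwise(df, spec, delta=2.0)
        assert {"WV (end)", "D (end)"} <= set(model.terms)
        assert len(model.terms) <= 3
        # AIC bookkeeping: each adoption records the exact evaluated change
        for h in history:
            assert h["aic_after"] == pytest.approx(h["aic_after"])
            assert not retain_complex(h["aic_before"], h["aic_after"])

    def test_pure_noise_collapses_to_empty_model(self):
        rng = np.random.default_rng(12)
        df = self.simulated_table(rng, n_strata=60, beta=(0.0,))
        df = df.rename(columns={"c0": "wv_end_z"})
        model, _ = backward_stepwise(df, ModelSpec(terms=["WV (end)"]), delta=2.0)
        assert model.terms == []
        assert "empty" in model.notes
        assert model.concordance == 0.5


class TestSpecAndDesign:
    @staticmethod
    def fish_table(rng, tods=("day", "dusk"), n_strata=40):
        cols = ["wv", "d", "svg", "diffvang", "diffsvgang"]
        rows = []
        for s in range(n_strata):
            tod = tods[s % len(tods)]
            start_vals = {f"{c}_start_z": rng.normal() for c in cols}
            for j in range(11):
                row = {"stratum": f"s{s:03d}", "case": j == 0, "tod": tod,
                       "temp_z": 0.3, "log_sl_z": rng.normal(),
                       "cos_ta_z": rng.normal()}
                row.update(start_vals)
                row.update({f"{c}_end_z": rng.normal() for c in cols})
                rows.append(row)
        return pd.DataFrame(rows)

    def test_saturated_universe_has_33_terms(self):
        assert len(saturated_term_labels(include_tod=True)) == 33
        assert len(saturated_term_labels(include_tod=False)) == 27

    def test_multi_tod_fish_keeps_tod_terms(self):
        df = self.fish_table(np.random.default_rng(13))
        spec = saturated_spec_for_fish(df)
        assert any("TOD" in t for t in spec.terms)
        assert len(spec.terms) == 33

    def test_single_tod_fish_drops_tod_terms(self):
        df = self.fish_table(np.random.default_rng(14), tods=("day",))
        spec = saturated_spec_for_fish(df)
        assert not any("TOD" in t for t in spec.terms)
        assert len(spec.terms) == 27

    def test_interaction_column_is_rowwise_product(self):
        df = self.fish_table(np.random.default_rng(15))
        d = build_design(df, ModelSpec(terms=["WV (end)", "D (end)",
                                              "WV (end):D (end)"]))
        j = d.column_labels.index("WV (end):D (end)")
        srt = df.sort_values("stratum", kind="stable")
        expected = srt["wv_end_z"].to_numpy() * srt["d_end_z"].to_numpy()
        assert np.allclose(d.X[:, j], expected)

    def test_design_has_eleven_rows_per_stratum(self):
        df = self.fish_table(np.random.default_rng(16))
        d = build_design(df, ModelSpec(terms=["WV (end)"]))
        assert (d.group_sizes == 11).all()

    def test_tod_expands_to_indicator_contrasts(self):
        df = self.fish_table(np.random.default_rng(17), tods=("day", "dusk"))
        d = build_design(df, ModelSpec(terms=["WV (end)", "TOD (end):WV (end)"],
                                       reference_tod="day"))
        assert "TOD (end):WV (end)[dusk]" in d.column_labels
        assert len(d.column_labels) == 2  # one non-reference category

    def test_tod_main_effect_rejected(self):
        df = self.fish_table(np.random.default_rng(18))
        with pytest.raises(DesignError, match="interactions"):
            build_design(df, ModelSpec(terms=["TOD (end)"]))

    def test_start_only_main_effect_rejected_as_constant(self):
        df = self.fish_table(np.random.default_rng(19))
        with pytest.raises(DesignError, match="constant within every stratum"):
            build_design(df, ModelSpec(terms=["WV (start)"]))

    def test_missing_column_names_the_covariate(self):
        df = self.fish_table(np.random.default_rng(20)).drop(columns=["svg_end_z"])
        with pytest.raises(DesignError, match="svg_end_z"):
            build_design(df, ModelSpec(terms=["SVG (end)"]))


class TestCorrelationScreen:
    def test_duplicated_column_flagged(self):
        rng = np.random.default_rng(21)
        a = rng.normal(size=500)
        df = pd.DataFrame({"a": a, "b": a.copy(), "c": rng.normal(size=500)})
        rep = correlation_screen(df)
        row = rep.query("col_a == 'a' and col_b == 'b'").iloc[0]
        assert row["r"] == pytest.approx(1.0) and row["flagged"]

    def test_independent_columns_not_flagged(self):
        rng = np.random.default_rng(22)
        df = pd.DataFrame(rng.normal(size=(10_000, 4)),
                          columns=["a", "b", "c", "d"])
        rep = correlation_screen(df)
        assert rep["r"].abs().max() < 0.05
        assert not rep["flagged"].any()

    def test_start_end_pair_exempt(self):
        rng = np.random.default_rng(23)
        x = rng.normal(size=2000)
        df = pd.DataFrame({"wv_start": x, "wv_end": 0.9 * x + 0.3 * rng.normal(size=2000)})
        rep = correlation_screen(df)
        row = rep.iloc[0]
        assert abs(row["r"]) > 0.5 and row["exempt"] and not row["flagged"]

    def test_constant_column_reported_undefined(self):
        df = pd.DataFrame({"a": np.ones(100), "b": np.arange(100.0)})
        rep = correlation_screen(df)
        assert np.isnan(rep["r"].iloc[0])
        assert "constant" in rep["note"].iloc[0]
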