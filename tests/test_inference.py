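"""Conditional-logistic inference tests: exact likelihood against
enumeration and numerical derivatives, Newton fitting, an independent
statsmodels cross-check, and the interaction-measure algebra."""

import math

import numpy as np
import pandas as pd
import pytest

import heatsmoke as hs
from heatsmoke.inference import (
    DegenerateDesignError,
    FitResult,
    NonConvergedError,
    StratumStructureError,
    conditional_loglik,
    interaction_measures,
)


def _design(rows):
    """rows: (stratum_id, is_case, x_heat, x_smoke)"""
    return pd.DataFrame(rows, columns=["stratum_id", "is_case", "x_heat", "x_smoke"])


def enumeration_loglik(beta, design):
    """Independent oracle: plain-Python conditional probability per stratum."""
    bH, bS, bHS = beta
    total = 0.0
    for _, grp in design.groupby("stratum_id"):
        etas = [
            bH * xh + bS * xs + bHS * xh * xs
            for xh, xs in zip(grp["x_heat"], grp["x_smoke"])
        ]
        case_eta = [e for e, c in zip(etas, grp["is_case"]) if c]
        assert len(case_eta) == 1
        total += case_eta[0] - math.log(math.fsum(math.exp(e) for e in etas))
    return total


def random_strata(rng, n_strata, max_rows=6):
    rows = []
    for s in range(n_strata):
        m = int(rng.integers(2, max_rows + 1))
        case = int(rng.integers(m))
        for i in range(m):
            rows.append(
                (s, i == case, float(rng.integers(0, 2)),
                 float(rng.exponential(5.0) * (rng.random() < 0.4)))
            )
    return _design(rows)


class TestConditionalLoglik:
    def test_uniform_at_null(self):
        d = _design([(0, i == 0, 1.0, 2.0 * i) for i in range(5)])
        ll, grad, hess = conditional_loglik(np.zeros(3), d)
        assert ll == pytest.approx(math.log(1 / 5))

    def test_one_to_one_pair_closed_form(self):
        d = _design([(0, True, 1.0, 0.0), (0, False, 0.0, 0.0)])
        for b in (-1.0, 0.3, 2.0):
            ll, grad, _ = conditional_loglik([b, 0.0, 0.0], d)
            assert ll == pytest.approx(b - math.log(1 + math.exp(b)))

    def test_matches_enumeration_oracle(self, rng):
        d = random_strata(rng, 50)
        for _ in range(5):
            beta = rng.normal(0, 0.5, 3)
            ll, grad, hess = conditional_loglik(beta, d)
            assert ll == pytest.approx(enumeration_loglik(beta, d), rel=1e-12)

    def test_gradient_matches_central_differences(self, rng):
        d = random_strata(rng, 40)
        beta = rng.normal(0, 0.3, 3)
        ll, grad, hess = conditional_loglik(beta, d)
        h = 1e-6
        for j in range(3):
            e = np.zeros(3)
            e[j] = h
            up, _, _ = conditional_loglik(beta + e, d)
            dn, _, _ = conditional_loglik(beta - e, d)
            assert grad[j] == pytest.approx((up - dn) / (2 * h), rel=1e-5, abs=1e-7)

    def test_hessian_matches_gradient_differences(self, rng):
        d = random_strata(rng, 40)
        beta = rng.normal(0, 0.3, 3)
        _, _, hess = conditional_loglik(beta, d)
        h = 1e-6
        for j in range(3):
            e = np.zeros(3)
            e[j] = h
            _, gu, _ = conditional_loglik(beta + e, d)
            _, gd, _ = conditional_loglik(beta - e, d)
            assert np.allclose(hess[:, j], (gu - gd) / (2 * h), rtol=1e-4, atol=1e-6)

    def test_noninformative_stratum_constant_contribution(self):
        d = _design([(0, i == 0, 1.0, 3.0) for i in range(4)])
        for beta in ([0.0, 0.0, 0.0], [1.0, -0.5, 0.2]):
            ll, grad, _ = conditional_loglik(beta, d)
            assert ll == pytest.approx(math.log(1 / 4))
            assert np.allclose(grad, 0.0)

    def test_two_cases_in_stratum_rejected(self):
        d = _design([(0, True, 1, 0), (0, True, 0, 0), (0, False, 0, 1)])
        with pytest.raises(StratumStructureError):
            conditional_loglik(np.zeros(3), d)


class TestFitClogit:
    def test_recovers_truth_on_large_simulation(self, rng):
        truth = (0.3, 0.05, 0.08)
        d = hs.simulate_strata(20_000, truth, rng)
        fit = hs.fit_clogit(d)
        assert fit.converged
        assert np.all(np.abs(fit.beta - truth) < 3 * fit.se)

    def test_duplicating_strata_halves_covariance(self, rng):
        d = hs.simulate_strata(2_000, (0.3, 0.05, 0.08), rng)
        fit1 = hs.fit_clogit(d)
        d2 = d.copy()
        d2["stratum_id"] = d2["stratum_id"] + d["stratum_id"].max() + 1
        fit2 = hs.fit_clogit(pd.concat([d, d2], ignore_index=True))
        assert np.allclose(fit1.beta, fit2.beta, atol=1e-7)
        assert np.allclose(fit2.covariance, fit1.covariance / 2, rtol=1e-6)

    def test_all_zero_exposures_refused(self):
        d = _design([(s, i == 0, 0.0, 0.0) for s in range(10) for i in range(4)])
        with pytest.raises(DegenerateDesignError):
            hs.fit_clogit(d)

    def test_separation_flagged_not_divergent(self, rng):
        # case always heat-exposed, referents never: monotone likelihood in
        # the heat coefficient; smoke varies freely so it stays identifiable
        d = _design(
            [
                (s, i == 0, float(i == 0), float(rng.exponential(5.0)))
                for s in range(30)
                for i in range(4)
            ]
        )
        fit = hs.fit_clogit(d)
        assert not fit.converged
        assert "separation" in fit.message or "monotone" in fit.message

    def test_structurally_collinear_term_named(self):
        # smoke identically zero: the smoke term cannot be identified
        d = _design(
            [(s, i == 0, float(i % 2), 0.0) for s in range(10) for i in range(4)]
        )
        with pytest.raises(hs.inference.SingularHessianError, match="x_smoke"):
            hs.fit_clogit(d)

    def test_cross_check_against_statsmodels(self, rng):
        """Independent reference: statsmodels' conditional likelihood."""
        from statsmodels.discrete.conditional_models import ConditionalLogit

        d = hs.simulate_strata(3_000, (0.4, 0.06, 0.1), rng)
        fit = hs.fit_clogit(d)
        X = np.column_stack(
            [d["x_heat"], d["x_smoke"], d["x_heat"] * d["x_smoke"]]
        )
        sm_fit = ConditionalLogit(
            d["is_case"].astype(int).to_numpy(), X, groups=d["stratum_id"].to_numpy()
        ).fit(disp=False)
        # statsmodels' optimizer stops at a looser tolerance than the Newton
        # fit, so agreement is to ~1e-4, not machine precision
        assert np.allclose(fit.beta, sm_fit.params, atol=5e-4)
        assert np.allclose(fit.se, sm_fit.bse, rtol=1e-3)

    def test_noninformative_strata_counted(self, rng):
        informative = hs.simulate_strata(100, (0.3, 0.05, 0.08), rng)
        flat = _design(
            [(1000 + s, i == 0, 0.0, 0.0) for s in range(20) for i in range(4)]
        )
        fit = hs.fit_clogit(pd.concat([informative, flat], ignore_index=True))
        assert fit.n_strata_dropped_noninformative >= 20


class TestInteractionMeasures:
    def _fit(self, beta, cov=None):
        cov = np.eye(3) * 1e-4 if cov is None else cov
        return FitResult(
            beta=np.asarray(beta, dtype=float), covariance=cov, loglik=0.0,
            converged=True, n_strata_used=100,
            n_strata_dropped_noninformative=0,
        )

    def test_or_arithmetic_example(self):
        # (OR01, OR10, OR11) = (1.2, 1.5, 2.0) -> RERI = 0.3, AP = 0.15
        bH, bS = math.log(1.2), math.log(1.5)
        bHS = math.log(2.0) - bH - bS
        est = interaction_measures(self._fit([bH, bS, bHS]), delta=1.0)
        assert est.or01.estimate == pytest.approx(1.2)
        assert est.or10.estimate == pytest.approx(1.5)
        assert est.or11.estimate == pytest.approx(2.0)
        assert est.reri.estimate == pytest.approx(0.3)
        assert est.ap.estimate == pytest.approx(0.15)

    def test_multiplicative_null_identity(self):
        # bHS = 0: OR11 = OR01*OR10, multiplicative = 1, RERI = (OR01-1)(OR10-1)
        bH, bS = math.log(1.4), math.log(1.3)
        est = interaction_measures(self._fit([bH, bS, 0.0]), delta=1.0)
        assert est.multiplicative.estimate == pytest.approx(1.0)
        assert est.or11.estimate == pytest.approx(1.4 * 1.3)
        assert est.reri.estimate == pytest.approx(0.4 * 0.3)
        assert est.reri.estimate >= 0

    def test_ap_or11_identity_and_sign_coherence(self, rng):
        for _ in range(20):
            beta = rng.normal(0, 0.4, 3)
            est = interaction_measures(self._fit(beta), delta=1.0)
            assert est.ap.estimate * est.or11.estimate == pytest.approx(
                est.reri.estimate, rel=1e-12, abs=1e-15
            )
            super_add = est.or11.estimate > (
                est.or01.estimate + est.or10.estimate - 1
            )
            assert (est.reri.estimate > 0) == super_add
            assert (est.ap.estimate > 0) == (est.reri.estimate > 0)

    def test_scale_equivariance_in_delta(self, rng):
        """Measures at delta = 2 equal measures of a refit with smoke
        rescaled by one half, evaluated at delta = 1."""
        d = hs.simulate_strata(4_000, (0.3, 0.05, 0.08), rng)
        fit = hs.fit_clogit(d)
        est2 = interaction_measures(fit, delta=2.0)
        d_half = d.copy()
        d_half["x_smoke"] = d_half["x_smoke"] / 2.0
        fit_half = hs.fit_clogit(d_half)
        est1 = interaction_measures(fit_half, delta=1.0)
        for name in ("or01", "or10", "or11", "multiplicative", "reri", "ap"):
            a, b = getattr(est2, name), getattr(est1, name)
            assert a.estimate == pytest.approx(b.estimate, rel=1e-6)
            assert a.ci_low == pytest.approx(b.ci_low, rel=1e-5)
            assert a.ci_high == pytest.approx(b.ci_high, rel=1e-5)

    def test_additive_null_centers_reri_at_zero(self, rng):
        """When the generator enforces exact additivity OR11 = OR01 + OR10 - 1
        (binary exposures, interaction coefficient solved accordingly), the
        estimated RERI is centered on zero."""
        bH, bS = 0.4, 0.3
        or11 = math.exp(bH) + math.exp(bS) - 1.0
        bHS = math.log(or11) - bH - bS
        reris = []
        for _ in range(30):
            d = hs.simulate_strata(3_000, (bH, bS, bHS), rng,
                                   binary_smoke=True, smoke_prob=0.25,
                                   heat_prob=0.25)
            fit = hs.fit_clogit(d)
            if fit.converged:
                reris.append(interaction_measures(fit, delta=1.0).reri.estimate)
        mean = np.mean(reris)
        sem = np.std(reris, ddof=1) / math.sqrt(len(reris))
        assert abs(mean) < 3 * sem + 0.01

    def test_nonconverged_fit_refused(self):
        fit = FitResult(
            beta=np.zeros(3), covariance=np.full((3, 3), np.nan), loglik=0.0,
            converged=False, n_strata_used=0,
            n_strata_dropped_noninformative=0, message="separation",
        )
        with pytest.raises(NonConvergedError):
            interaction_measures(fit)

    def test_wald_ci_for_heat_or(self):
        cov = np.diag([0.01, 0.0, 0.0])
        est = interaction_measures(self._fit([0.2, 0.0, 0.0], cov))
        assert est.or01.ci_low == pytest.approx(math.exp(0.2 - 1.96 * 0.1), rel=1e-3)
        assert est.or01.ci_high == pytest.approx(math.exp(0.2 + 1.96 * 0.1), rel=1e-3)
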