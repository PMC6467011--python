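"""Kinetics: rates, Kramers forward model, ratio curves, barrier decomposition."""

import math

import numpy as np
import pandas as pd
import pytest

import pairswitch as ps
from pairswitch.constants import EULER_GAMMA, KB_KCAL_MOL_K
from pairswitch.dwell import (
    LifetimeStats,
    LifetimeSummary,
    mean_lifetimes,
    segments_from_path,
    transition_path_times,
)
from pairswitch.kinetics import (
    barrier_fit,
    kramers_times,
    rate_constants,
    ratio_curves,
)
from pairswitch.synthetic import simulate_path
from pairswitch.thermo import ThermoFit


def summary_of(**taus):
    return LifetimeSummary(
        {label: LifetimeStats(tau, 10) for label, tau in taus.items()}
    )


class TestRateConstants:
    def test_dissociation_rate_is_reciprocal_association_lifetime(self):
        rates = rate_constants(summary_of(A=2.0))
        assert rates.k_minus == 0.5
        assert rates.k_plus is None

    def test_rate_ratio_equals_lifetime_ratio(self):
        rates = rate_constants(summary_of(A=2.0, D=4.0))
        assert rates.k_plus / rates.k_minus == pytest.approx(0.5)

    def test_transition_rate_mapping(self):
        summary = summary_of(ata=0.004, dtd=0.005, dta=0.01, atd=0.02)
        printed = rate_constants(summary, transition_mapping="printed")
        assert printed.k_t_to_a == pytest.approx(1 / 0.004)
        assert printed.k_t_to_d == pytest.approx(1 / 0.005)
        crossing = rate_constants(summary, transition_mapping="crossing")
        assert crossing.k_t_to_a == pytest.approx(1 / 0.01)
        assert crossing.k_t_to_d == pytest.approx(1 / 0.02)

    def test_detailed_balance_on_generator(self, small_ensemble):
        # k+/k- from ground-truth lifetimes matches p_a/p_d
        for T in small_ensemble.temperatures():
            path = small_ensemble[T].path
            summary = mean_lifetimes(segments_from_path(path), n_boot=0)
            rates = rate_constants(summary)
            lhs = rates.k_plus / rates.k_minus
            rhs = path.state_time("A") / path.state_time("D")
            n = min(summary["A"].n, summary["D"].n)
            assert lhs == pytest.approx(rhs, abs=3 * rhs * np.sqrt(2.0 / n))


class TestKramersTimes:
    ARGS = dict(
        dGa_kcal_mol=-4.95,
        dGd_kcal_mol=-3.59,
        omega_ratio_a=0.05,
        omega_ratio_d=0.08,
        omega_star=1.0,
        T=530.0,
    )

    def test_ratios_independent_of_diffusion_coefficient(self):
        a = kramers_times(D_star=100.0, **self.ARGS)
        b = kramers_times(D_star=7.0, **self.ARGS)
        assert a.r_a == pytest.approx(b.r_a, rel=1e-12)
        assert a.r_d == pytest.approx(b.r_d, rel=1e-12)
        assert a.t_a_ns != b.t_a_ns  # absolute times do scale

    def test_doubling_barrier_multiplies_dwell_time_exponentially(self):
        base = kramers_times(D_star=100.0, **self.ARGS)
        args = dict(self.ARGS, dGa_kcal_mol=2 * self.ARGS["dGa_kcal_mol"])
        doubled = kramers_times(D_star=100.0, **args)
        beta = 1.0 / (KB_KCAL_MOL_K * self.ARGS["T"])
        assert doubled.t_a_ns / base.t_a_ns == pytest.approx(
            math.exp(beta * abs(self.ARGS["dGa_kcal_mol"])), rel=1e-12
        )

    def test_matches_independent_formula_evaluation(self):
        # duplicate implementation, written out longhand
        kt = kramers_times(D_star=250.0, **self.ARGS)
        beta = 1.0 / (KB_KCAL_MOL_K * self.ARGS["T"])
        denom = beta * 250.0 * 1.0**2
        t_a = 2 * math.pi * 0.05 * math.exp(beta * 4.95) / denom
        t_tp_ad = math.log(2 * math.exp(EULER_GAMMA) * beta * 4.95) / denom
        t_tp_da = math.log(2 * math.exp(EULER_GAMMA) * beta * 3.59) / denom
        assert kt.t_a_ns == pytest.approx(t_a, rel=1e-12)
        assert kt.t_tp_ad_ns == pytest.approx(t_tp_ad, rel=1e-12)
        assert kt.t_tp_da_ns == pytest.approx(t_tp_da, rel=1e-12)

    def test_vanishing_barrier_rejected(self):
        # beta|dG| <= 1/(2 e^gamma) makes the transition-path log negative
        with pytest.raises(ValueError):
            kramers_times(-0.1, -3.0, 0.05, 0.08, 1.0, 1.0, 530.0)


class TestRatioCurves:
    def test_elementwise_ratio(self):
        summary = summary_of(A=10.0, D=4.0)
        from pairswitch.dwell import TransitionPathTimes

        per_T = {
            530.0: (
                summary,
                TransitionPathTimes(t_tp_da_ns=0.2, t_tp_ad_ns=0.1, n_da=5, n_ad=5),
            )
        }
        curves = ratio_curves(per_T)
        assert curves.loc[0, "r_a"] == pytest.approx(100.0)
        assert curves.loc[0, "r_d"] == pytest.approx(20.0)

    def test_missing_ingredient_omits_temperature_with_warning(self):
        from pairswitch.dwell import TransitionPathTimes

        good = (
            summary_of(A=10.0, D=4.0),
            TransitionPathTimes(t_tp_da_ns=0.2, t_tp_ad_ns=0.1, n_da=5, n_ad=5),
        )
        bad = (
            summary_of(A=10.0, D=4.0),
            TransitionPathTimes(t_tp_da_ns=None, t_tp_ad_ns=0.1, n_da=0, n_ad=5),
        )
        with pytest.warns(UserWarning, match="540"):
            curves = ratio_curves({530.0: good, 540.0: bad})
        assert curves["temperature_K"].tolist() == [530.0]


def forward_ratios(thermo, s_tilde_eu, omega_a, omega_d, temperatures):
    rows = []
    for T in temperatures:
        dGd = T * s_tilde_eu / 1000.0
        kt = kramers_times(thermo.dG(T) + dGd, dGd, omega_a, omega_d, 100.0, 1.0, T)
        rows.append({"temperature_K": T, "r_a": kt.r_a, "r_d": kt.r_d})
    return pd.DataFrame(rows)


class TestBarrierFit:
    THERMO = ThermoFit.from_parameters(-4.95, -6.78)
    TEMPS = (530.0, 540.0, 560.0, 580.0)

    @pytest.mark.parametrize(
        "s_tilde, omega_a, omega_d",
        [(-6.78, 0.05, 0.08), (-9.0, 0.02, 0.3), (-5.0, 1.0, 1.0)],
    )
    def test_noiseless_round_trip(self, s_tilde, omega_a, omega_d):
        ratios = forward_ratios(self.THERMO, s_tilde, omega_a, omega_d, self.TEMPS)
        fit = barrier_fit(ratios, self.THERMO, seed=0)
        assert fit.dS_tilde_eu == pytest.approx(s_tilde, rel=1e-6)
        assert fit.omega_ratio_a == pytest.approx(omega_a, rel=1e-6)
        assert fit.omega_ratio_d == pytest.approx(omega_d, rel=1e-6)

    def test_entropic_barrier_equal_to_entropy_makes_dGa_the_enthalpy(self):
        ratios = forward_ratios(self.THERMO, self.THERMO.dS_eu, 0.05, 0.08, self.TEMPS)
        fit = barrier_fit(ratios, self.THERMO, seed=0)
        spread = max(fit.dGa_kcal_mol) - min(fit.dGa_kcal_mol)
        assert spread < 1e-9
        for g in fit.dGa_kcal_mol:
            assert g == pytest.approx(self.THERMO.dH_kcal_mol, abs=1e-9)

    def test_constant_r_d_reproduced_with_zero_residual(self):
        ratios = forward_ratios(self.THERMO, -6.0, 0.05, 0.08, self.TEMPS)
        assert np.ptp(ratios["r_d"].to_numpy()) < 1e-12  # model predicts constancy
        fit = barrier_fit(ratios, self.THERMO, seed=0)
        assert np.asarray(fit.predicted_r_d) == pytest.approx(
            ratios["r_d"].to_numpy(), rel=1e-9
        )

    def test_barrier_decomposition_constraint(self):
        ratios = forward_ratios(self.THERMO, -8.0, 0.1, 0.2, self.TEMPS)
        fit = barrier_fit(ratios, self.THERMO, seed=0)
        assert fit.constraint_residual < 1e-9
        for T, ga, gd in zip(fit.temperatures_K, fit.dGa_kcal_mol, fit.dGd_kcal_mol):
            assert ga - gd == pytest.approx(self.THERMO.dG(T), abs=1e-12)

    def test_needs_two_temperatures(self):
        ratios = forward_ratios(self.THERMO, -6.78, 0.05, 0.08, (530.0,))
        with pytest.raises(ValueError):
            barrier_fit(ratios, self.THERMO, seed=0)

    def test_end_to_end_recovery_within_bootstrap_ci(self):
        """Kramers-driven switching paths at 4 temperatures: the fitted
        (dS~, curvature ratios) must bracket the generating values within
        the parametric-bootstrap confidence interval of the ratio curves.
        The barrier entropy is weakly identified (the amplitude trades off
        against it except through the ln ln term), so the CI is wide; the
        check is that the inference is calibrated, not that it is sharp."""
        truth = dict(s_tilde=-6.78, omega_a=0.05, omega_d=0.08)
        scale = 500.0  # D* w*^2, kcal/mol/ns: dwell times ~0.03-0.07 ns
        per_T = {}
        for T in self.TEMPS:
            dGd = T * truth["s_tilde"] / 1000.0
            kt = kramers_times(
                self.THERMO.dG(T) + dGd, dGd, truth["omega_a"], truth["omega_d"],
                scale, 1.0, T,
            )
            rng = np.random.default_rng([17, int(T)])
            path = simulate_path(
                kt.t_a_ns, kt.t_d_ns, kt.t_tp_ad_ns, kt.t_tp_da_ns, 0.0, 400.0, rng
            )
            segs = segments_from_path(path)
            per_T[T] = (
                mean_lifetimes(segs, n_boot=100, seed=21),
                transition_path_times(segs, n_boot=100, seed=22),
            )
        ratios = ratio_curves(per_T)
        rng = np.random.default_rng(23)
        boot = []
        for _ in range(100):
            pert = ratios.copy()
            for col in ("r_a", "r_d"):
                rel_se = ratios[f"se_{col}"] / ratios[col]
                pert[col] = np.exp(
                    np.log(ratios[col]) + rng.normal(size=len(ratios)) * rel_se
                )
            fit = barrier_fit(pert, self.THERMO, seed=0)
            boot.append((fit.dS_tilde_eu, fit.omega_ratio_a, fit.omega_ratio_d))
        boot = np.asarray(boot)
        for i, key in enumerate(("s_tilde", "omega_a", "omega_d")):
            lo, hi = np.percentile(boot[:, i], [2.5, 97.5])
            assert lo <= truth[key] <= hi, f"{key}: truth outside [{lo}, {hi}]"
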