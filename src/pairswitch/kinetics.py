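"""Rates, Kramers transition-path-time theory, and barrier decomposition.

Rate constants come straight from mean lifetimes: the association rate is
``k+ = 1/tau_ave^d``, the dissociation rate ``k- = 1/tau_ave^a``, and the
transition-state exit rates are ``k_{t->a} = 1/tau_ave^{ata}`` and
``k_{t->d} = 1/tau_ave^{dtd}``.

On a one-dimensional free-energy surface with barrier-top diffusion
coefficient ``D*`` and curvatures ``(w*)^2`` (top), ``(w_a)^2``,
``(w_d)^2`` (basins), the high-barrier mean dwell and transition-path
times are

    t_a      = 2 pi exp(beta |dG_a|) / (beta D* w* w_a)
    t_d      = 2 pi exp(beta |dG_d|) / (beta D* w* w_d)
    t_tp^da  = ln(2 e^gamma beta |dG_d|) / (beta D* (w*)^2)
    t_tp^ad  = ln(2 e^gamma beta |dG_a|) / (beta D* (w*)^2)

with ``beta = 1/(kB T)`` and ``gamma`` Euler's constant.  The ratios
``r_a = t_a / t_tp^{a->d}`` and ``r_d = t_d / t_tp^{d->a}`` are
independent of ``D*`` and of the absolute curvature scale; they depend
only on the barrier heights and the curvature ratios ``w*/w_a``,
``w*/w_d``.  Fitting the two ratio curves against temperature under the
constraint ``dG_d = T dS~`` (an entropic association barrier, which makes
``r_d`` temperature independent) decomposes the equilibrium free energy
``dG = dG_a - dG_d`` into its two barriers; when ``dS~`` equals the
van't Hoff entropy, ``dG_a(T) = dH`` exactly.

Sign convention: barrier values are book-kept with the signs the
equilibrium decomposition gives them (they can be negative); magnitudes
``|dG|`` enter the exponential and logarithm where a height is required.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .constants import EU_PER_KCAL_MOL_K, EULER_GAMMA, KB_KCAL_MOL_K
from .dwell import LifetimeSummary, TransitionPathTimes
from .thermo import ThermoFit

__all__ = [
    "RateSet",
    "KramersTimes",
    "KineticsFit",
    "rate_constants",
    "kramers_times",
    "ratio_curves",
    "barrier_fit",
]

# ln argument 2 e^gamma beta|dG| must exceed 1 for a positive t_tp
_MIN_BETA_DG = 1.0 / (2.0 * math.exp(EULER_GAMMA))


@dataclass(frozen=True)
class RateSet:
    """Rate constants (1/ns) derived from mean lifetimes; absent -> None."""

    k_plus: float | None  # association, 1/tau_ave^d
    k_minus: float | None  # dissociation, 1/tau_ave^a
    k_t_to_a: float | None
    k_t_to_d: float | None


def rate_constants(
    summary: LifetimeSummary, transition_mapping: str = "printed"
) -> RateSet:
    """Reciprocal mean lifetimes as rate constants.

    ``transition_mapping="printed"`` uses the failed-crossing episodes
    (``k_{t->a} = 1/tau^{ata}``, ``k_{t->d} = 1/tau^{dtd}``);
    ``"crossing"`` uses the successful ones (dta/atd) instead.
    """
    if transition_mapping not in ("printed", "crossing"):
        raise ValueError("transition_mapping must be 'printed' or 'crossing'")
    to_a, to_d = (
        ("ata", "dtd") if transition_mapping == "printed" else ("dta", "atd")
    )

    def inv(label: str) -> float | None:
        s = summary.get(label)
        return 1.0 / s.tau_ave_ns if s and s.tau_ave_ns > 0 else None

    return RateSet(
        k_plus=inv("D"), k_minus=inv("A"), k_t_to_a=inv(to_a), k_t_to_d=inv(to_d)
    )


@dataclass(frozen=True)
class KramersTimes:
    t_a_ns: float
    t_d_ns: float
    t_tp_da_ns: float
    t_tp_ad_ns: float

    @property
    def r_a(self) -> float:
        return self.t_a_ns / self.t_tp_ad_ns

    @property
    def r_d(self) -> float:
        return self.t_d_ns / self.t_tp_da_ns


def _log_ratio_model(abs_beta_dG: float, omega_ratio: float) -> float:
    """ln of t_basin/t_tp for one basin; D* and w* cancel."""
    ln_arg = 2.0 * math.exp(EULER_GAMMA) * abs_beta_dG
    return (
        math.log(2.0 * math.pi * omega_ratio)
        + abs_beta_dG
        - math.log(math.log(ln_arg))
    )


def kramers_times(
    dGa_kcal_mol: float,
    dGd_kcal_mol: float,
    omega_ratio_a: float,
    omega_ratio_d: float,
    D_star: float,
    omega_star: float,
    T: float,
) -> KramersTimes:
    """Forward model for mean dwell and transition-path times (ns).

    ``omega_ratio_a`` and ``omega_ratio_d`` are ``w*/w_a`` and ``w*/w_d``;
    ``D_star`` and ``omega_star`` set absolute scale only (``D* w*^2`` in
    kcal mol^-1 ns^-1 gives times in ns) — every reported ratio is
    independent of them.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    if omega_ratio_a <= 0 or omega_ratio_d <= 0 or D_star <= 0 or omega_star <= 0:
        raise ValueError("curvature and diffusion parameters must be positive")
    beta = 1.0 / (KB_KCAL_MOL_K * T)
    x_a, x_d = abs(dGa_kcal_mol) * beta, abs(dGd_kcal_mol) * beta
    for name, x in (("dG_a", x_a), ("dG_d", x_d)):
        if x <= _MIN_BETA_DG:
            raise ValueError(
                f"beta|{name}| = {x:.4g} <= 1/(2 e^gamma); transition-path log "
                "argument is non-positive"
            )
    # D* w*^2 in kcal mol^-1 ns^-1 makes beta*scale an inverse time in ns^-1
    scale = beta * D_star * omega_star**2
    t_tp_da = math.log(2.0 * math.exp(EULER_GAMMA) * x_d) / scale
    t_tp_ad = math.log(2.0 * math.exp(EULER_GAMMA) * x_a) / scale
    t_a = 2.0 * math.pi * omega_ratio_a * math.exp(x_a) / scale
    t_d = 2.0 * math.pi * omega_ratio_d * math.exp(x_d) / scale
    return KramersTimes(t_a, t_d, t_tp_da, t_tp_ad)


def ratio_curves(
    per_temperature: dict[float, tuple[LifetimeSummary, TransitionPathTimes]],
) -> pd.DataFrame:
    """Lifetime/transition-path-time ratios r_a, r_d per temperature.

    Temperatures missing any of the four ingredients are omitted with a
    warning.  Bootstrap standard errors, where available, are propagated
    in quadrature on the relative scale.
    """
    rows = []
    for T in sorted(per_temperature):
        summary, tpt = per_temperature[T]
        t_a = summary.get("A")
        t_d = summary.get("D")
        if t_a is None or t_d is None or tpt.t_tp_ad_ns is None or tpt.t_tp_da_ns is None:
            warnings.warn(
                f"temperature {T} K lacks a lifetime or transition-path time; omitted"
            )
            continue
        r_a = t_a.tau_ave_ns / tpt.t_tp_ad_ns
        r_d = t_d.tau_ave_ns / tpt.t_tp_da_ns
        rows.append(
            {
                "temperature_K": T,
                "r_a": r_a,
                "r_d": r_d,
                "se_r_a": _ratio_se(r_a, t_a.tau_ave_ns, t_a.se_ns, tpt.t_tp_ad_ns, tpt.se_ad_ns),
                "se_r_d": _ratio_se(r_d, t_d.tau_ave_ns, t_d.se_ns, tpt.t_tp_da_ns, tpt.se_da_ns),
            }
        )
    return pd.DataFrame(rows)


def _ratio_se(r, num, se_num, den, se_den):
    if se_num is None or se_den is None:
        return None
    return abs(r) * math.sqrt((se_num / num) ** 2 + (se_den / den) ** 2)


@dataclass(frozen=True)
class KineticsFit:
    """Barrier decomposition fitted from the two ratio curves."""

    dS_tilde_eu: float  # entropic association barrier: dG_d = T dS~
    omega_ratio_a: float
    omega_ratio_d: float
    temperatures_K: tuple[float, ...]
    dGa_kcal_mol: tuple[float, ...]  # per temperature, signed
    dGd_kcal_mol: tuple[float, ...]
    dGa_mean_kcal_mol: float
    predicted_r_a: tuple[float, ...]
    predicted_r_d: tuple[float, ...]
    log_residuals: tuple[float, ...]
    cost: float
    constraint_residual: float  # max |dG_a - dG_d - dG(T)|

    def report(self) -> dict:
        return {
            "dS_tilde_eu": self.dS_tilde_eu,
            "omega_ratio_a": self.omega_ratio_a,
            "omega_ratio_d": self.omega_ratio_d,
            "dGa_mean_kcal_mol": self.dGa_mean_kcal_mol,
            "per_temperature": [
                {
                    "temperature_K": T,
                    "dGa_kcal_mol": ga,
                    "dGd_kcal_mol": gd,
                    "predicted_r_a": ra,
                    "predicted_r_d": rd,
                }
                for T, ga, gd, ra, rd in zip(
                    self.temperatures_K,
                    self.dGa_kcal_mol,
                    self.dGd_kcal_mol,
                    self.predicted_r_a,
                    self.predicted_r_d,
                )
            ],
            "cost": self.cost,
            "constraint_residual": self.constraint_residual,
        }


def _barriers(thermo: ThermoFit, T: np.ndarray, s_mag: float, sign: float):
    """Signed (dG_a, dG_d) under dG_d = T dS~ and dG_a = dG + dG_d."""
    dGd = sign * T * s_mag
    dG = np.array([thermo.dG(t) for t in T])
    return dG + dGd, dGd


def _profile_cost(
    s_mag: float,
    thermo: ThermoFit,
    sign: float,
    T: np.ndarray,
    log_ra: np.ndarray,
    log_rd: np.ndarray,
):
    """Residual cost at barrier entropy magnitude ``s_mag`` with the
    amplitude (curvature-ratio) parameters profiled out in closed form."""
    beta = 1.0 / (KB_KCAL_MOL_K * T)
    dGa, dGd = _barriers(thermo, T, s_mag, sign)
    x_a, x_d = np.abs(dGa) * beta, np.abs(dGd) * beta
    if np.any(x_a <= _MIN_BETA_DG) or np.any(x_d <= _MIN_BETA_DG):
        return np.inf, (math.nan, math.nan), None
    base_a = x_a - np.log(np.log(2.0 * math.exp(EULER_GAMMA) * x_a))
    base_d = x_d - np.log(np.log(2.0 * math.exp(EULER_GAMMA) * x_d))
    # optimal log-amplitude is the mean log offset
    log_amp_a = float(np.mean(log_ra - base_a))
    log_amp_d = float(np.mean(log_rd - base_d))
    res = np.concatenate([log_ra - base_a - log_amp_a, log_rd - base_d - log_amp_d])
    amp_a = math.exp(log_amp_a) / (2.0 * math.pi)
    amp_d = math.exp(log_amp_d) / (2.0 * math.pi)
    return float(res @ res), (amp_a, amp_d), res


def barrier_fit(
    ratios: pd.DataFrame,
    thermo: ThermoFit,
    seed: int = 0,
    s_bounds_eu: tuple[float, float] = (0.05, 60.0),
) -> KineticsFit:
    """Fit (dS~, w*/w_a, w*/w_d) to the measured ratio curves.

    The model is ``r_d(T) = 2 pi (w*/w_d) exp(beta|dG_d|) / ln(2 e^gamma
    beta|dG_d|)`` with ``dG_d = T dS~`` (hence r_d constant in T) and the
    analogous ``r_a(T)`` with ``dG_a = dG(T) + dG_d``.  Residuals are on
    the log-ratio scale.  The two amplitude parameters enter linearly in
    log space and are profiled out exactly; the remaining 1-D problem in
    ``|dS~|`` is bracketed on a grid and minimised by bounded Brent
    search, then polished with Levenberg-Marquardt least squares (seeded
    restarts from perturbed starting points guard against local minima).

    The sign of ``dS~`` follows the van't Hoff entropy, and
    ``dG_a - dG_d = dG(T)`` holds identically in the output.
    """
    if len(ratios) < 2:
        raise ValueError("barrier fit needs ratios at >= 2 temperatures")
    T = ratios["temperature_K"].to_numpy(dtype=float)
    r_a = ratios["r_a"].to_numpy(dtype=float)
    r_d = ratios["r_d"].to_numpy(dtype=float)
    if np.any(r_a <= 0) or np.any(r_d <= 0):
        raise ValueError("ratios must be positive")
    if np.ptp(r_a) == 0 and np.ptp(r_d) == 0 and len(ratios) > 2:
        warnings.warn("ratio curves are flat; barrier entropy is weakly identified")
    log_ra, log_rd = np.log(r_a), np.log(r_d)
    sign = -1.0 if thermo.dS_eu < 0 else 1.0
    lo, hi = (b / EU_PER_KCAL_MOL_K for b in s_bounds_eu)

    def cost(s):
        return _profile_cost(s, thermo, sign, T, log_ra, log_rd)[0]

    # bracket on a log grid, then Brent
    grid = np.geomspace(lo, hi, 200)
    costs = np.array([cost(s) for s in grid])
    s0 = float(grid[int(np.argmin(costs))])
    res = optimize.minimize_scalar(
        cost,
        bounds=(max(lo, s0 / 3.0), min(hi, s0 * 3.0)),
        method="bounded",
        options={"xatol": 1e-14},
    )
    s_best = float(res.x)

    # LM polish over (s, log amplitudes), seeded perturbed restarts
    rng = np.random.default_rng(seed)
    _, (amp_a0, amp_d0), _ = _profile_cost(s_best, thermo, sign, T, log_ra, log_rd)

    def residuals(theta):
        s, la, ld = theta
        if not lo <= abs(s) <= hi:
            return np.full(2 * len(T), 1e6)
        c, _, res_vec = _profile_cost(abs(s), thermo, sign, T, log_ra, log_rd)
        if res_vec is None:
            return np.full(2 * len(T), 1e6)
        beta = 1.0 / (KB_KCAL_MOL_K * T)
        dGa, dGd = _barriers(thermo, T, abs(s), sign)
        x_a, x_d = np.abs(dGa) * beta, np.abs(dGd) * beta
        base_a = x_a - np.log(np.log(2.0 * math.exp(EULER_GAMMA) * x_a))
        base_d = x_d - np.log(np.log(2.0 * math.exp(EULER_GAMMA) * x_d))
        return np.concatenate(
            [log_ra - base_a - la - math.log(2 * math.pi), log_rd - base_d - ld - math.log(2 * math.pi)]
        )

    best_theta = np.array([s_best, math.log(amp_a0), math.log(amp_d0)])
    best_cost = cost(s_best)
    for attempt in range(3):
        x0 = best_theta if attempt == 0 else best_theta * (
            1.0 + 0.2 * rng.standard_normal(3)
        )
        try:
            sol = optimize.least_squares(
                residuals, x0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15
            )
        except Exception:
            continue
        if sol.cost * 2.0 < best_cost and lo <= abs(sol.x[0]) <= hi:
            best_cost = sol.cost * 2.0
            best_theta = sol.x.copy()
    s_best = min(max(abs(float(best_theta[0])), lo), hi)
    total_cost, (amp_a, amp_d), res_vec = _profile_cost(
        s_best, thermo, sign, T, log_ra, log_rd
    )
    dGa, dGd = _barriers(thermo, T, s_best, sign)
    beta = 1.0 / (KB_KCAL_MOL_K * T)
    x_a, x_d = np.abs(dGa) * beta, np.abs(dGd) * beta
    pred_ra = 2 * math.pi * amp_a * np.exp(x_a) / np.log(2 * math.exp(EULER_GAMMA) * x_a)
    pred_rd = 2 * math.pi * amp_d * np.exp(x_d) / np.log(2 * math.exp(EULER_GAMMA) * x_d)
    dG = np.array([thermo.dG(t) for t in T])
    constraint = float(np.max(np.abs(dGa - dGd - dG)))
    return KineticsFit(
        dS_tilde_eu=sign * s_best * EU_PER_KCAL_MOL_K,
        omega_ratio_a=amp_a,
        omega_ratio_d=amp_d,
        temperatures_K=tuple(T.tolist()),
        dGa_kcal_mol=tuple(dGa.tolist()),
        dGd_kcal_mol=tuple(dGd.tolist()),
        dGa_mean_kcal_mol=float(np.mean(dGa)),
        predicted_r_a=tuple(pred_ra.tolist()),
        predicted_r_d=tuple(pred_rd.tolist()),
        log_residuals=tuple(res_vec.tolist()),
        cost=total_cost,
        constraint_residual=constraint,
    )
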