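"""Van't Hoff thermodynamics from state occupancies across temperatures.

The free-energy difference between the open and closed basin is obtained
from the two-state occupancy ratio, ``DG(T) = kB T ln(p_d/p_a)``
(transition and unassigned frames are excluded from the ratio, not
renormalised into it).  Plotting ``ln(p_d/p_a)`` against ``1/T`` is
linear when ``DG = DH - T DS`` with constant enthalpy and entropy:

    ln(p_d/p_a) = (DH/kB) (1/T) - DS/kB

so an ordinary least-squares line gives ``DH = slope * kB`` and
``DS = -intercept * kB``, and ``DG`` extrapolates to any temperature
(e.g. physiological 310 K) as ``DH - T DS``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import EU_PER_KCAL_MOL_K, KB_KCAL_MOL_K

__all__ = ["ThermoFit", "free_energy", "vant_hoff_fit", "extrapolate_dG", "gibbs_free_energy"]


def free_energy(p_a: float, p_d: float, T: float) -> float:
    """Two-state free-energy difference kB T ln(p_d/p_a), kcal/mol."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    if p_a <= 0 or p_d <= 0:
        raise ValueError(
            f"free energy undefined for non-positive occupancy (p_a={p_a}, p_d={p_d}); "
            "both basins must be visited"
        )
    return KB_KCAL_MOL_K * T * math.log(p_d / p_a)


def gibbs_free_energy(dH_kcal_mol: float, dS_eu: float, T: float) -> float:
    """DG = DH - T DS with DS supplied in entropy units, kcal/mol."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    return dH_kcal_mol - T * dS_eu / EU_PER_KCAL_MOL_K


@dataclass(frozen=True)
class ThermoFit:
    """Result of the van't Hoff regression."""

    dH_kcal_mol: float
    dS_eu: float
    slope: float  # of ln(p_d/p_a) vs 1/T, equals dH/kB
    intercept: float  # equals -dS/kB
    r_squared: float
    temperatures_K: tuple[float, ...]
    ln_ratio: tuple[float, ...]
    residuals: tuple[float, ...]

    @classmethod
    def from_parameters(cls, dH_kcal_mol: float, dS_eu: float) -> "ThermoFit":
        """A fit object holding stated parameters (no regression performed)."""
        return cls(
            dH_kcal_mol=dH_kcal_mol,
            dS_eu=dS_eu,
            slope=dH_kcal_mol / KB_KCAL_MOL_K,
            intercept=-dS_eu / (KB_KCAL_MOL_K * EU_PER_KCAL_MOL_K),
            r_squared=float("nan"),
            temperatures_K=(),
            ln_ratio=(),
            residuals=(),
        )

    def dG(self, T: float) -> float:
        return gibbs_free_energy(self.dH_kcal_mol, self.dS_eu, T)

    def per_temperature(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "temperature_K": self.temperatures_K,
                "ln_pd_over_pa": self.ln_ratio,
                "dG_kcal_mol": [
                    KB_KCAL_MOL_K * T * y
                    for T, y in zip(self.temperatures_K, self.ln_ratio)
                ],
                "residual": self.residuals,
            }
        )

    def report(self) -> dict:
        return {
            "dH_kcal_mol": self.dH_kcal_mol,
            "dS_eu": self.dS_eu,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "per_temperature": self.per_temperature().to_dict(orient="records"),
            "dG_310K_kcal_mol": self.dG(310.0),
        }


def vant_hoff_fit(
    points: list[tuple[float, float, float]],
    weights: list[float] | None = None,
) -> ThermoFit:
    """Fit ln(p_d/p_a) against 1/T by (optionally weighted) least squares.

    Parameters
    ----------
    points : (T_K, p_a, p_d) triples, one per temperature.
    weights : optional per-point weights (e.g. inverse bootstrap variances
        of the log-ratio); ``None`` gives the ordinary unweighted fit.
    """
    if len(points) < 2:
        raise ValueError("van't Hoff fit needs at least two temperatures")
    T = np.asarray([p[0] for p in points], dtype=float)
    if np.unique(T).size < 2:
        raise ValueError("temperatures are collinear (need >= 2 distinct values)")
    for t, p_a, p_d in points:
        _check_occ(p_a, p_d, t)
    y = np.array([math.log(p_d / p_a) for _, p_a, p_d in points])
    x = 1.0 / T
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != x.shape or np.any(w <= 0):
        raise ValueError("weights must be positive, one per point")
    sw = np.sqrt(w)
    design = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    fitted = design @ coef
    residuals = y - fitted
    ss_res = float(np.sum(w * residuals**2))
    ss_tot = float(np.sum(w * (y - np.average(y, weights=w)) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return ThermoFit(
        dH_kcal_mol=slope * KB_KCAL_MOL_K,
        dS_eu=-intercept * KB_KCAL_MOL_K * EU_PER_KCAL_MOL_K,
        slope=slope,
        intercept=intercept,
        r_squared=r_squared,
        temperatures_K=tuple(T.tolist()),
        ln_ratio=tuple(y.tolist()),
        residuals=tuple(residuals.tolist()),
    )


def _check_occ(p_a: float, p_d: float, T: float) -> tuple[float, float]:
    if T <= 0:
        raise ValueError("temperature must be positive")
    if p_a <= 0 or p_d <= 0:
        raise ValueError(
            f"occupancies must be positive at T={T} (p_a={p_a}, p_d={p_d})"
        )
    return p_a, p_d


def extrapolate_dG(fit: ThermoFit, T: float) -> float:
    """DG = DH - T DS at temperature ``T`` (kcal/mol), from a fit's parameters."""
    return fit.dG(T)
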