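"""Synthetic two-state switching trajectories with transition episodes.

The generator is a continuous-time Markov model of a terminal base pair
that alternates between an association (closed, ``A``) and a dissociation
(open, ``D``) basin.  Every basin exit passes through a short transition
episode (``T``); an episode either commits to the other basin or falls
back into the basin it came from (an ``ata``/``dtd`` event).  Basin dwell
times and episode durations are exponential.  The mean dissociation-state
lifetime is implied by the association lifetime and the Boltzmann
equilibrium constant, so the long-run ratio of open to closed time obeys
the configured enthalpy/entropy at every temperature.

Each frame of the emitted trajectory carries the observables used for
state classification downstream: RMSD of the guide base, target base and
the pair (angstrom) and the backbone torsion zeta of both strands
(degrees).  Observables are drawn from state-conditional truncated
distributions; the guide base is emitted from closed-like distributions
in *every* state, reproducing the preorganisation of the seed base.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .constants import EU_PER_KCAL_MOL_K, KB_KCAL_MOL_K

__all__ = [
    "TruncatedDist",
    "EmissionParams",
    "PathSegment",
    "StatePath",
    "GeneratorConfig",
    "TrajectoryRun",
    "TemperatureEnsemble",
    "equilibrium_ratio",
    "association_lifetime",
    "simulate_state_path",
    "emit_observables",
    "simulate_ensemble",
]

TRAJECTORY_COLUMNS = [
    "time_ps",
    "rmsd_pair_A",
    "rmsd_guide_A",
    "rmsd_target_A",
    "zeta_guide_deg",
    "zeta_target_deg",
]

# purpose codes for named RNG streams: (seed, round(T*1000), purpose)
_STREAM_PATH = 0
_STREAM_EMISSION = 1


def equilibrium_ratio(dH_kcal_mol: float, dS_eu: float, T: float) -> float:
    """Equilibrium occupancy ratio p_d/p_a at temperature ``T``.

    Follows ``DG = kB T ln(p_d/p_a)`` with ``DG = DH - T DS``, i.e.
    ``p_d/p_a = exp[(DH - T DS) / (kB T)]``.

    Parameters
    ----------
    dH_kcal_mol : enthalpy change (association minus dissociation), kcal/mol.
    dS_eu : entropy change in entropy units (cal mol^-1 K^-1).
    T : absolute temperature, K.
    """
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    dG = dH_kcal_mol - T * dS_eu / EU_PER_KCAL_MOL_K
    return math.exp(dG / (KB_KCAL_MOL_K * T))


@dataclass(frozen=True)
class TruncatedDist:
    """A truncated emission distribution for one observable in one state.

    ``kind`` is ``"normal"`` (mean ``loc``, sd ``scale``) or
    ``"shifted_gamma"`` (``loc`` + Gamma(``shape``, ``scale``)); samples are
    restricted to ``(lower, upper]`` bounds (rejection for the gamma).
    """

    kind: str
    loc: float
    scale: float
    lower: float
    upper: float
    shape: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("normal", "shifted_gamma"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if self.kind == "shifted_gamma" and self.shape is None:
            raise ValueError("shifted_gamma requires a shape parameter")
        if not self.lower < self.upper:
            raise ValueError("lower bound must be below upper bound")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if n == 0:
            return np.empty(0)
        if self.kind == "normal":
            if self.scale == 0.0:
                return np.full(n, float(self.loc))
            a = (self.lower - self.loc) / self.scale
            b = (self.upper - self.loc) / self.scale
            return stats.truncnorm.rvs(
                a, b, loc=self.loc, scale=self.scale, size=n, random_state=rng
            )
        # shifted gamma, truncated by rejection (tail mass is tiny for defaults)
        out = np.empty(n)
        filled = 0
        while filled < n:
            draw = self.loc + rng.gamma(self.shape, self.scale, size=n - filled)
            ok = draw[(draw > self.lower) & (draw <= self.upper)]
            out[filled : filled + ok.size] = ok
            filled += ok.size
        return out

    def mean(self) -> float:
        if self.kind == "normal":
            return self.loc
        return self.loc + self.shape * self.scale


def _closed_rmsd() -> TruncatedDist:
    return TruncatedDist("normal", loc=0.7, scale=0.15, lower=0.0, upper=2.0)


def _open_rmsd() -> TruncatedDist:
    return TruncatedDist("shifted_gamma", loc=2.0, scale=0.8, shape=2.0, lower=2.0, upper=12.0)


def _closed_zeta() -> TruncatedDist:
    return TruncatedDist("normal", loc=-75.0, scale=8.0, lower=-100.0, upper=-50.0)


def _open_zeta() -> TruncatedDist:
    return TruncatedDist("normal", loc=70.0, scale=10.0, lower=50.0, upper=100.0)


@dataclass(frozen=True)
class EmissionParams:
    """State-conditional emission distributions for the five observables.

    Keys of each mapping are the basin/episode states ``"A"``, ``"D"``,
    ``"T"``.  The transition state combines open-like RMSD with
    closed-like zeta; the guide base is closed-like in every state
    (seed preorganisation).
    """

    rmsd_pair: dict[str, TruncatedDist]
    rmsd_guide: dict[str, TruncatedDist]
    rmsd_target: dict[str, TruncatedDist]
    zeta_guide: dict[str, TruncatedDist]
    zeta_target: dict[str, TruncatedDist]

    @classmethod
    def default(cls) -> "EmissionParams":
        closed_like_rmsd = {"A": _closed_rmsd(), "D": _open_rmsd(), "T": _open_rmsd()}
        guide_rmsd = {s: _closed_rmsd() for s in "ADT"}
        zeta_target = {"A": _closed_zeta(), "D": _open_zeta(), "T": _closed_zeta()}
        zeta_guide = {s: _closed_zeta() for s in "ADT"}
        return cls(
            rmsd_pair=closed_like_rmsd,
            rmsd_guide=guide_rmsd,
            rmsd_target=dict(closed_like_rmsd),
            zeta_guide=zeta_guide,
            zeta_target=zeta_target,
        )

    def features(self) -> dict[str, dict[str, TruncatedDist]]:
        return {
            "rmsd_pair_A": self.rmsd_pair,
            "rmsd_guide_A": self.rmsd_guide,
            "rmsd_target_A": self.rmsd_target,
            "zeta_guide_deg": self.zeta_guide,
            "zeta_target_deg": self.zeta_target,
        }


@dataclass(frozen=True)
class PathSegment:
    """One contiguous dwell of the ground-truth state path."""

    state: str  # "A", "D" or "T"
    start_ns: float
    duration_ns: float
    origin: str | None = None  # for T segments: basin the episode left
    destination: str | None = None  # for T segments: basin it entered


@dataclass
class StatePath:
    """Ground-truth state path: contiguous segments covering [0, total_time]."""

    segments: list[PathSegment]
    total_time_ns: float

    def __post_init__(self) -> None:
        t = 0.0
        prev_state = None
        for seg in self.segments:
            if not math.isclose(seg.start_ns, t, rel_tol=0.0, abs_tol=1e-9):
                raise ValueError("segments are not contiguous")
            if seg.duration_ns <= 0:
                raise ValueError("segment durations must be positive")
            if seg.state == prev_state:
                raise ValueError("consecutive segments share a state label")
            prev_state = seg.state
            t += seg.duration_ns
        if not math.isclose(t, self.total_time_ns, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError("segments do not cover [0, total_time]")

    def state_time(self, state: str) -> float:
        return sum(s.duration_ns for s in self.segments if s.state == state)

    def episode_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.segments:
            if s.state == "T" and s.origin and s.destination:
                key = f"{s.origin.lower()}t{s.destination.lower()}"
                counts[key] = counts.get(key, 0) + 1
        return counts

    def frame_labels(self, frame_dt_ps: float) -> np.ndarray:
        """State active at each frame time (frames at 0, dt, 2dt, ...)."""
        n = int(round(self.total_time_ns * 1000.0 / frame_dt_ps))
        t_ns = np.arange(n) * (frame_dt_ps / 1000.0)
        starts = np.array([s.start_ns for s in self.segments])
        idx = np.searchsorted(starts, t_ns, side="right") - 1
        states = np.array([s.state for s in self.segments])
        return states[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "state": [s.state for s in self.segments],
                "origin": [s.origin or "" for s in self.segments],
                "destination": [s.destination or "" for s in self.segments],
                "start_ns": [s.start_ns for s in self.segments],
                "duration_ns": [s.duration_ns for s in self.segments],
            }
        )


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic switching ensemble.

    Defaults mirror the simulated system: temperatures 530-580 K, frames
    every 2 ps, 4000 ns per temperature and the with-protein
    thermodynamics (dH=-4.95 kcal/mol, dS=-6.78 eu).  Basin lifetimes
    follow an Arrhenius law anchored at ``T_ref_K``; the activation
    energy default equals |dH| so the open-state lifetime is nearly
    temperature independent, reproducing the observed asymmetry between
    the two basins.
    """

    temperatures_K: tuple[float, ...] = (530.0, 540.0, 560.0, 580.0)
    dH_kcal_mol: float = -4.95
    dS_eu: float = -6.78
    tau_assoc_ref_ns: float = 0.05
    T_ref_K: float = 530.0
    assoc_lifetime_activation: float = 4.95  # kcal/mol
    tau_tp_ns: float = 0.004
    p_fail: float = 0.3
    frame_dt_ps: float = 2.0
    total_time_ns: float = 4000.0
    emission: EmissionParams = field(default_factory=EmissionParams.default)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.temperatures_K) < 1:
            raise ValueError("at least one temperature is required")
        if any(T <= 0 for T in self.temperatures_K):
            raise ValueError("temperatures must be positive")
        if self.total_time_ns < 100.0 * self.tau_tp_ns:
            raise ValueError("total_time_ns must be at least 100 x tau_tp_ns")
        if not 0.0 <= self.p_fail < 1.0:
            raise ValueError("p_fail must lie in [0, 1)")
        if self.frame_dt_ps <= 0:
            raise ValueError("frame_dt_ps must be positive")
        if self.tau_assoc_ref_ns <= 0 or self.tau_tp_ns <= 0:
            raise ValueError("lifetimes must be positive")
        if self.T_ref_K <= 0:
            raise ValueError("T_ref_K must be positive")

    def with_(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)


def association_lifetime(config: GeneratorConfig, T: float) -> float:
    """Mean closed-state lifetime tau_a(T), Arrhenius in temperature (ns)."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    ea = config.assoc_lifetime_activation
    return config.tau_assoc_ref_ns * math.exp(
        (ea / KB_KCAL_MOL_K) * (1.0 / T - 1.0 / config.T_ref_K)
    )


def _stream(seed: int, T: float, purpose: int) -> np.random.Generator:
    """Named RNG stream keyed on (seed, temperature, purpose).

    Adding or reordering temperatures never perturbs another
    temperature's stream.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int(round(T * 1000.0)), purpose])
    )


def simulate_path(
    tau_a_ns: float,
    tau_d_ns: float,
    tau_tp_ad_ns: float,
    tau_tp_da_ns: float,
    p_fail: float,
    total_time_ns: float,
    rng: np.random.Generator,
    start_state: str = "A",
) -> StatePath:
    """Simulate the alternating basin/episode path with explicit means.

    Episodes leaving A use ``tau_tp_ad_ns`` (both committed atd and failed
    ata), episodes leaving D use ``tau_tp_da_ns``.  The final segment is
    truncated at ``total_time_ns``.
    """
    if start_state not in ("A", "D"):
        raise ValueError("start_state must be 'A' or 'D'")
    segments: list[PathSegment] = []
    t = 0.0
    basin = start_state
    taus = {"A": tau_a_ns, "D": tau_d_ns}
    tp_taus = {"A": tau_tp_ad_ns, "D": tau_tp_da_ns}
    while t < total_time_ns:
        dwell = rng.exponential(taus[basin])
        segments.append(PathSegment(basin, t, min(dwell, total_time_ns - t)))
        t += dwell
        if t >= total_time_ns:
            break
        episode = rng.exponential(tp_taus[basin])
        other = "D" if basin == "A" else "A"
        dest = basin if rng.random() < p_fail else other
        segments.append(
            PathSegment("T", t, min(episode, total_time_ns - t), origin=basin, destination=dest)
        )
        t += episode
        basin = dest
    return StatePath(segments, total_time_ns)


def simulate_state_path(
    config: GeneratorConfig, T: float, rng: np.random.Generator
) -> StatePath:
    """Simulate the ground-truth path at temperature ``T``.

    The open-state mean lifetime is tied to the closed-state one through
    the equilibrium constant, ``tau_d = (p_d/p_a) tau_a``, so basin-time
    ratios converge to the configured Boltzmann equilibrium.
    """
    tau_a = association_lifetime(config, T)
    tau_d = equilibrium_ratio(config.dH_kcal_mol, config.dS_eu, T) * tau_a
    return simulate_path(
        tau_a,
        tau_d,
        config.tau_tp_ns,
        config.tau_tp_ns,
        config.p_fail,
        config.total_time_ns,
        rng,
    )


def emit_observables(
    path: StatePath,
    emission: EmissionParams,
    frame_dt_ps: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw per-frame observables from the state active at each frame.

    Returns the standard trajectory table with columns ``time_ps``,
    ``rmsd_pair_A``, ``rmsd_guide_A``, ``rmsd_target_A``,
    ``zeta_guide_deg``, ``zeta_target_deg``.
    """
    labels = path.frame_labels(frame_dt_ps)
    n = labels.size
    out = pd.DataFrame({"time_ps": np.arange(n) * frame_dt_ps})
    masks = {s: labels == s for s in "ADT"}
    for column, dists in emission.features().items():
        values = np.empty(n)
        for state, mask in masks.items():
            values[mask] = dists[state].sample(rng, int(mask.sum()))
        out[column] = values
    return out


@dataclass
class TrajectoryRun:
    """One temperature's synthetic run: observables plus ground truth."""

    temperature_K: float
    trajectory: pd.DataFrame
    path: StatePath


@dataclass
class TemperatureEnsemble:
    """Synthetic runs indexed by temperature, with the generating config."""

    config: GeneratorConfig
    runs: dict[float, TrajectoryRun]

    def temperatures(self) -> list[float]:
        return sorted(self.runs)

    def __getitem__(self, T: float) -> TrajectoryRun:
        return self.runs[T]


def simulate_ensemble(config: GeneratorConfig) -> TemperatureEnsemble:
    """Simulate one trajectory per configured temperature.

    Each (temperature, purpose) pair draws from its own named RNG stream
    derived from ``config.seed``, so ensembles are reproducible and
    extensible without perturbing existing members.
    """
    runs: dict[float, TrajectoryRun] = {}
    for T in config.temperatures_K:
        path = simulate_state_path(config, T, _stream(config.seed, T, _STREAM_PATH))
        traj = emit_observables(
            path, config.emission, config.frame_dt_ps, _stream(config.seed, T, _STREAM_EMISSION)
        )
        runs[T] = TrajectoryRun(T, traj, path)
    return TemperatureEnsemble(config, runs)
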