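"""Dwell-time and occupancy statistics from a classified state sequence.

Occupancies follow the time-fraction definition ``p_x = sum_i tau_i^x / tau``
with ``tau`` the total observation time; transition-episode time counts
toward ``p_t`` only.  Mean lifetimes are plain arithmetic means
``tau_ave = sum_i tau_i / N``; dwells touching the start or end of the
sequence are censored from basin lifetime averages (but not from
occupancy), and transition-path times are the mean durations of the
*successful* crossing episodes (``dta`` for open->closed, ``atd`` for
closed->open).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import StateSequence, run_length_encode

__all__ = [
    "DwellSegment",
    "OccupancyResult",
    "LifetimeStats",
    "LifetimeSummary",
    "TransitionPathTimes",
    "segment",
    "segments_from_path",
    "occupancy",
    "cumulative_occupancy",
    "mean_lifetimes",
    "lifetime_histogram",
    "transition_path_times",
]


@dataclass(frozen=True)
class DwellSegment:
    """One contiguous dwell: state label, optional episode type, duration."""

    label: str  # A | D | T | U
    start_ns: float
    duration_ns: float
    index: int
    episode: str | None = None  # for T segments: ata/dtd/atd/dta/edge


@dataclass(frozen=True)
class OccupancyResult:
    p_a: float
    p_d: float
    p_t: float
    p_u: float
    total_time_ns: float

    def as_dict(self) -> dict[str, float]:
        return {
            "p_a": self.p_a,
            "p_d": self.p_d,
            "p_t": self.p_t,
            "p_u": self.p_u,
            "total_time_ns": self.total_time_ns,
        }


@dataclass(frozen=True)
class LifetimeStats:
    tau_ave_ns: float
    n: int
    se_ns: float | None = None


@dataclass
class LifetimeSummary:
    """Mean lifetimes per state label and per transition-episode type.

    Only labels/episode types that actually occur are present.
    """

    stats: dict[str, LifetimeStats]

    def __contains__(self, key: str) -> bool:
        return key in self.stats

    def __getitem__(self, key: str) -> LifetimeStats:
        return self.stats[key]

    def get(self, key: str) -> LifetimeStats | None:
        return self.stats.get(key)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": list(self.stats),
                "tau_ave_ns": [s.tau_ave_ns for s in self.stats.values()],
                "N": [s.n for s in self.stats.values()],
                "se_ns": [s.se_ns for s in self.stats.values()],
            }
        )


def segment(seq: StateSequence) -> list[DwellSegment]:
    """Run-length encode the label sequence into dwell segments.

    Durations are frame counts times the frame interval; transition runs
    carry their episode annotation when the sequence has one.
    """
    dt_ns = seq.frame_dt_ps / 1000.0
    episode_by_start = {e.start_frame: e.kind for e in seq.episodes}
    out = []
    for i, (label, start, length) in enumerate(run_length_encode(seq.labels)):
        out.append(
            DwellSegment(
                label=label,
                start_ns=start * dt_ns,
                duration_ns=length * dt_ns,
                index=i,
                episode=episode_by_start.get(start) if label == "T" else None,
            )
        )
    return out


def segments_from_path(path) -> list[DwellSegment]:
    """Dwell segments straight from a ground-truth generator path."""
    out = []
    for i, seg in enumerate(path.segments):
        episode = None
        if seg.state == "T" and seg.origin and seg.destination:
            episode = f"{seg.origin.lower()}t{seg.destination.lower()}"
        out.append(DwellSegment(seg.state, seg.start_ns, seg.duration_ns, i, episode))
    return out


def occupancy(segments: list[DwellSegment], total_time_ns: float) -> OccupancyResult:
    """Occupied probability of each state as its time fraction of ``total_time_ns``."""
    if total_time_ns <= 0:
        raise ValueError("total_time_ns must be positive")
    covered = sum(s.duration_ns for s in segments)
    if covered > total_time_ns * (1 + 1e-9):
        raise ValueError("segments cover more than the stated total time")
    time = {lab: 0.0 for lab in "ADTU"}
    for s in segments:
        time[s.label] += s.duration_ns
    return OccupancyResult(
        p_a=time["A"] / total_time_ns,
        p_d=time["D"] / total_time_ns,
        p_t=time["T"] / total_time_ns,
        p_u=time["U"] / total_time_ns,
        total_time_ns=total_time_ns,
    )


def cumulative_occupancy(seq: StateSequence, stride: int = 1) -> pd.DataFrame:
    """Running occupancy p_a on [0, t] for every ``stride``-th frame.

    The last row always uses the full sequence, so its ``p_a`` equals
    ``occupancy(segment(seq), seq.total_time_ns).p_a`` exactly.
    """
    if seq.n_frames == 0:
        raise ValueError("empty sequence")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    is_a = (seq.labels == "A").astype(np.int64)
    cum = np.cumsum(is_a)
    idx = np.arange(seq.n_frames)
    keep = np.union1d(idx[stride - 1 :: stride], [seq.n_frames - 1])
    dt_ns = seq.frame_dt_ps / 1000.0
    return pd.DataFrame(
        {
            "time_ns": (keep + 1) * dt_ns,
            "p_a": cum[keep] / (keep + 1),
        }
    )


def _bootstrap_se(
    durations: np.ndarray, n_boot: int, rng: np.random.Generator
) -> float | None:
    if durations.size < 2 or n_boot < 1:
        return None
    idx = rng.integers(0, durations.size, size=(n_boot, durations.size))
    return float(np.std(durations[idx].mean(axis=1), ddof=1))


def mean_lifetimes(
    segments: list[DwellSegment],
    censor_edges: bool = True,
    n_boot: int = 1000,
    seed: int = 0,
) -> LifetimeSummary:
    """Arithmetic-mean lifetime, count and bootstrap SE per label/episode.

    Basin (A/D) averages exclude the first and last segments of the
    sequence when ``censor_edges`` (those dwells are truncated by the
    observation window); ``edge`` transition episodes are likewise
    excluded from episode-type averages but reported under ``"edge"``.
    """
    rng = np.random.default_rng(seed)
    groups: dict[str, list[float]] = {}
    last = len(segments) - 1
    for i, s in enumerate(segments):
        censored = censor_edges and (i == 0 or i == last)
        if s.label in ("A", "D", "U"):
            if not censored:
                groups.setdefault(s.label, []).append(s.duration_ns)
        elif s.label == "T":
            if not censored:
                groups.setdefault("T", []).append(s.duration_ns)
            if s.episode:
                if s.episode == "edge" or censored:
                    groups.setdefault("edge", []).append(s.duration_ns)
                else:
                    groups.setdefault(s.episode, []).append(s.duration_ns)
    stats = {}
    for label, values in groups.items():
        arr = np.asarray(values)
        stats[label] = LifetimeStats(
            tau_ave_ns=float(arr.mean()),
            n=int(arr.size),
            se_ns=_bootstrap_se(arr, n_boot, rng),
        )
    return LifetimeSummary(stats)


def lifetime_histogram(
    segments: list[DwellSegment],
    label: str,
    bin_edges: np.ndarray | None = None,
    n_bins: int = 20,
    min_edge_ns: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of dwell durations for one label or episode type.

    Default bins are logarithmically spaced from the shortest observed
    dwell (or ``min_edge_ns``) to the longest; counts sum to N.
    """
    durations = np.asarray(
        [
            s.duration_ns
            for s in segments
            if s.label == label or (s.episode == label and label not in "ADTU")
        ]
    )
    if durations.size == 0:
        raise ValueError(f"no dwells with label {label!r}")
    if bin_edges is None:
        lo = min_edge_ns if min_edge_ns is not None else durations.min()
        hi = durations.max()
        if not lo < hi:
            hi = lo * (1 + 1e-9) + 1e-12
        bin_edges = np.geomspace(max(lo, 1e-12), hi, n_bins + 1)
        bin_edges[0] = min(bin_edges[0], durations.min())
        bin_edges[-1] = max(bin_edges[-1], durations.max())
    else:
        bin_edges = np.asarray(bin_edges, dtype=float)
        if np.any(np.diff(bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
    counts, edges = np.histogram(durations, bins=bin_edges)
    return counts, edges


@dataclass(frozen=True)
class TransitionPathTimes:
    """Mean transition-path times; a direction with no crossing is None."""

    t_tp_da_ns: float | None  # open -> closed (dta episodes)
    t_tp_ad_ns: float | None  # closed -> open (atd episodes)
    n_da: int = 0
    n_ad: int = 0
    se_da_ns: float | None = None
    se_ad_ns: float | None = None


def transition_path_times(
    segments: list[DwellSegment], n_boot: int = 1000, seed: int = 0
) -> TransitionPathTimes:
    """Mean duration of successful crossing episodes per direction."""
    rng = np.random.default_rng(seed)
    out = {}
    for direction, episode in (("da", "dta"), ("ad", "atd")):
        durations = np.asarray(
            [s.duration_ns for s in segments if s.episode == episode]
        )
        if durations.size == 0:
            out[direction] = (None, 0, None)
        else:
            out[direction] = (
                float(durations.mean()),
                int(durations.size),
                _bootstrap_se(durations, n_boot, rng),
            )
    return TransitionPathTimes(
        t_tp_da_ns=out["da"][0],
        t_tp_ad_ns=out["ad"][0],
        n_da=out["da"][1],
        n_ad=out["ad"][1],
        se_da_ns=out["da"][2],
        se_ad_ns=out["ad"][2],
    )
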