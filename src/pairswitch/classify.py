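"""Hard-threshold conformational state classification and episode labelling.

Frames are mapped to four labels from the pair RMSD and the target-strand
backbone torsion zeta:

* ``A`` association/closed: RMSD <= 2 A and zeta in the closed window
  [-100, -50] degrees;
* ``D`` dissociation/open: RMSD > 2 A and zeta in the open window
  [50, 100] degrees;
* ``T`` transition: RMSD > 2 A while zeta is still in the closed window;
* ``U`` unassigned: anything else (zeta outside both windows, or a
  closed-like RMSD with an open-like zeta).

Maximal ``T`` runs are annotated by the basins they connect: ``ata`` and
``dtd`` are failed crossings (back to the originating basin), ``atd`` and
``dta`` are successful ones; runs touching a sequence boundary are
``edge`` and are excluded from kinetic averages.  ``U`` runs are
transparent when determining the flanking basins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ClassifierThresholds",
    "Episode",
    "StateSequence",
    "classify_frame",
    "classify_frames",
    "classify_trajectory",
    "annotate_episodes",
    "run_length_encode",
]


def wrap_angle_deg(angle):
    """Wrap angles (degrees) into (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    wrapped = -(np.mod(-a + 180.0, 360.0) - 180.0)
    return wrapped if wrapped.ndim else float(wrapped)


@dataclass(frozen=True)
class ClassifierThresholds:
    """Decision thresholds; defaults are the standard RMSD/zeta criteria."""

    rmsd_open_min: float = 2.0
    zeta_closed: tuple[float, float] = (-100.0, -50.0)
    zeta_open: tuple[float, float] = (50.0, 100.0)
    min_dwell_frames: int = 1
    max_gap_frames: int = 0
    use_target_rmsd: bool = False  # classify on rmsd_target instead of rmsd_pair

    def __post_init__(self) -> None:
        if self.rmsd_open_min <= 0:
            raise ValueError("rmsd_open_min must be positive")
        lo_c, hi_c = self.zeta_closed
        lo_o, hi_o = self.zeta_open
        if not (lo_c < hi_c and lo_o < hi_o):
            raise ValueError("zeta intervals must be non-empty")
        if max(lo_c, lo_o) <= min(hi_c, hi_o):
            raise ValueError("zeta windows must be disjoint")
        if self.min_dwell_frames < 1:
            raise ValueError("min_dwell_frames must be >= 1")
        if self.max_gap_frames < 0:
            raise ValueError("max_gap_frames must be >= 0")

    @property
    def rmsd_column(self) -> str:
        return "rmsd_target_A" if self.use_target_rmsd else "rmsd_pair_A"


@dataclass(frozen=True)
class Episode:
    """One annotated maximal T run."""

    kind: str  # ata | dtd | atd | dta | edge
    start_frame: int
    n_frames: int


@dataclass
class StateSequence:
    """Per-frame labels with frame spacing and transition-episode annotations."""

    labels: np.ndarray  # array of "A"/"D"/"T"/"U", one per frame
    frame_dt_ps: float
    episodes: list[Episode] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype="<U1")
        if self.frame_dt_ps <= 0:
            raise ValueError("frame_dt_ps must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.labels.size)

    @property
    def total_time_ns(self) -> float:
        return self.n_frames * self.frame_dt_ps / 1000.0

    def counts(self) -> dict[str, int]:
        vals, cnt = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), cnt.tolist()))

    def episode_table(self) -> pd.DataFrame:
        dt_ns = self.frame_dt_ps / 1000.0
        return pd.DataFrame(
            {
                "episode_type": [e.kind for e in self.episodes],
                "start_ns": [e.start_frame * dt_ns for e in self.episodes],
                "duration_ns": [e.n_frames * dt_ns for e in self.episodes],
            }
        )


def classify_frame(
    rmsd: float, zeta_target: float, thresholds: ClassifierThresholds | None = None
) -> str:
    """Classify a single frame from its RMSD (angstrom) and target zeta (deg)."""
    th = thresholds or ClassifierThresholds()
    if not (np.isfinite(rmsd) and np.isfinite(zeta_target)):
        raise ValueError("frame features must be finite")
    return str(
        classify_frames(np.asarray([rmsd]), np.asarray([zeta_target]), th)[0]
    )


def classify_frames(
    rmsd: np.ndarray, zeta_target: np.ndarray, thresholds: ClassifierThresholds
) -> np.ndarray:
    """Vectorised frame-wise classification (no smoothing)."""
    rmsd = np.asarray(rmsd, dtype=float)
    zeta = wrap_angle_deg(np.asarray(zeta_target, dtype=float))
    bad = ~(np.isfinite(rmsd) & np.isfinite(zeta))
    if bad.any():
        raise ValueError(
            f"non-finite features at frames {np.flatnonzero(bad)[:10].tolist()}"
        )
    lo_c, hi_c = thresholds.zeta_closed
    lo_o, hi_o = thresholds.zeta_open
    in_closed = (zeta >= lo_c) & (zeta <= hi_c)
    in_open = (zeta >= lo_o) & (zeta <= hi_o)
    is_open_rmsd = rmsd > thresholds.rmsd_open_min
    labels = np.full(rmsd.shape, "U", dtype="<U1")
    labels[~is_open_rmsd & in_closed] = "A"
    labels[is_open_rmsd & in_open] = "D"
    labels[is_open_rmsd & in_closed] = "T"
    return labels


def run_length_encode(labels: np.ndarray) -> list[tuple[str, int, int]]:
    """Maximal runs as (label, start_index, length)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return []
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    return [(str(labels[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


def _bridge_gaps(labels: np.ndarray, max_gap: int) -> np.ndarray:
    if max_gap < 1:
        return labels
    out = labels.copy()
    runs = run_length_encode(out)
    for i, (lab, start, length) in enumerate(runs):
        if lab != "U" or length > max_gap:
            continue
        if 0 < i < len(runs) - 1 and runs[i - 1][0] == runs[i + 1][0]:
            out[start : start + length] = runs[i - 1][0]
    return out


def _debounce(labels: np.ndarray, min_dwell: int) -> np.ndarray:
    if min_dwell <= 1:
        return labels
    out = labels.copy()
    while True:
        runs = run_length_encode(out)
        if len(runs) <= 1:
            return out
        victim = next(
            (i for i, (_, _, length) in enumerate(runs) if length < min_dwell), None
        )
        if victim is None:
            return out
        lab, start, length = runs[victim]
        left = runs[victim - 1] if victim > 0 else None
        right = runs[victim + 1] if victim < len(runs) - 1 else None
        # merge into the longer neighbour; ties and one-sided cases go left
        if left is not None and (right is None or left[2] >= right[2]):
            out[start : start + length] = left[0]
        else:
            out[start : start + length] = right[0]


def classify_trajectory(
    trajectory: pd.DataFrame, thresholds: ClassifierThresholds | None = None
) -> StateSequence:
    """Classify a feature table into a smoothed, episode-annotated sequence.

    Applies frame-wise thresholds, then bridges short unassigned gaps
    (``max_gap_frames``), then debounces runs shorter than
    ``min_dwell_frames`` into their longer neighbour.
    """
    th = thresholds or ClassifierThresholds()
    if len(trajectory) == 0:
        raise ValueError("trajectory is empty")
    dt = _infer_frame_dt_ps(trajectory)
    labels = classify_frames(
        trajectory[th.rmsd_column].to_numpy(),
        trajectory["zeta_target_deg"].to_numpy(),
        th,
    )
    labels = _bridge_gaps(labels, th.max_gap_frames)
    labels = _debounce(labels, th.min_dwell_frames)
    return annotate_episodes(StateSequence(labels, dt))


def _infer_frame_dt_ps(trajectory: pd.DataFrame) -> float:
    t = trajectory["time_ps"].to_numpy()
    if t.size < 2:
        return 1.0
    dt = float(np.median(np.diff(t)))
    if dt <= 0:
        raise ValueError("time_ps must be strictly increasing")
    return dt


def annotate_episodes(seq: StateSequence) -> StateSequence:
    """Label every maximal T run by its flanking basins.

    ``U`` runs are transparent when looking for the flanking basin; a T
    run with no basin on one side is ``edge``.
    """
    runs = run_length_encode(seq.labels)
    basin = {"A": "a", "D": "d"}
    episodes: list[Episode] = []
    for i, (lab, start, length) in enumerate(runs):
        if lab != "T":
            continue
        before = next(
            (basin[r[0]] for r in reversed(runs[:i]) if r[0] in basin), None
        )
        after = next((basin[r[0]] for r in runs[i + 1 :] if r[0] in basin), None)
        kind = f"{before}t{after}" if before and after else "edge"
        episodes.append(Episode(kind, start, length))
    seq.episodes = episodes
    return seq
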