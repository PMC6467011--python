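"""Per-frame observables from coordinates: RMSD and the backbone torsion zeta.

The zeta torsion is defined over the four backbone atoms
C3'(n)-O3'(n)-P(n+1)-O5'(n+1) with the IUPAC sign convention (cis = 0,
trans = 180 degrees).  RMSD is computed against the starting structure
*without* superposition: in a complex whose remainder is position
restrained, the laboratory frame is the reference frame.  An optional
least-squares fit is available for unrestrained systems.

Coordinates can come from a plain text table (columns ``frame``,
``atom``, ``x``, ``y``, ``z``; angstrom) or, when MDAnalysis is
installed, from any trajectory format it reads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AtomSelection",
    "DegenerateGeometryError",
    "dihedral",
    "rmsd",
    "extract_features",
    "read_coordinate_table",
    "features_from_universe",
]


class DegenerateGeometryError(ValueError):
    """Raised when a torsion is undefined (coincident points / collinear triple)."""


@dataclass(frozen=True)
class AtomSelection:
    """Atom identifiers defining the observables.

    ``guide_atoms``/``target_atoms`` are the (heavy) atoms of the two
    nucleotides entering the RMSDs; ``zeta_guide``/``zeta_target`` are the
    four ordered backbone atoms of each strand's torsion.
    """

    guide_atoms: tuple[str, ...]
    target_atoms: tuple[str, ...]
    zeta_guide: tuple[str, str, str, str]
    zeta_target: tuple[str, str, str, str]

    def __post_init__(self) -> None:
        if len(self.zeta_guide) != 4 or len(self.zeta_target) != 4:
            raise ValueError("torsion selections need exactly 4 ordered atoms")
        if not self.guide_atoms or not self.target_atoms:
            raise ValueError("RMSD selections must be non-empty")


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle (degrees, in (-180, 180]) of four points.

    Standard atan2 construction on the two plane normals; raises
    :class:`DegenerateGeometryError` for coincident consecutive points or
    a collinear bonded triple rather than returning a silent 0.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    scale = max(np.linalg.norm(b) for b in (b1, b2, b3))
    if scale == 0.0 or any(np.linalg.norm(b) < 1e-12 * scale for b in (b1, b2, b3)):
        raise DegenerateGeometryError("consecutive points coincide")
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    if (
        np.linalg.norm(n1) < 1e-10 * scale**2
        or np.linalg.norm(n2) < 1e-10 * scale**2
    ):
        raise DegenerateGeometryError("collinear bonded triple; torsion undefined")
    b2u = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2u))
    angle = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if angle <= -180.0 else angle


def rmsd(coords: np.ndarray, ref_coords: np.ndarray, superpose: bool = False) -> float:
    """Root-mean-square deviation (angstrom) over matched atom lists.

    No fitting is performed unless ``superpose=True`` (Kabsch least-squares
    alignment of ``coords`` onto ``ref_coords`` first).
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    ref = np.asarray(ref_coords, dtype=float).reshape(-1, 3)
    if coords.shape != ref.shape:
        raise ValueError(
            f"atom count mismatch: {coords.shape[0]} vs {ref.shape[0]}"
        )
    if superpose:
        coords = _kabsch_align(coords, ref)
    return float(np.sqrt(np.mean(np.sum((coords - ref) ** 2, axis=1))))


def _kabsch_align(mobile: np.ndarray, ref: np.ndarray) -> np.ndarray:
    mc, rc = mobile.mean(axis=0), ref.mean(axis=0)
    m, r = mobile - mc, ref - rc
    u, _, vt = np.linalg.svd(m.T @ r)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    return m @ rot + rc


def read_coordinate_table(path) -> pd.DataFrame:
    """Read a multi-frame coordinate table (TSV: frame, atom, x, y, z)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"frame", "atom", "x", "y", "z"} - set(df.columns)
    if missing:
        raise ValueError(f"coordinate table lacks columns {sorted(missing)}")
    return df


def _frame_coords(frame_df: pd.DataFrame, atoms: tuple[str, ...]) -> np.ndarray:
    lookup = {a: (x, y, z) for a, x, y, z in zip(
        frame_df["atom"], frame_df["x"], frame_df["y"], frame_df["z"]
    )}
    missing = [a for a in atoms if a not in lookup]
    if missing:
        raise ValueError(f"selection atoms missing from frame: {missing}")
    return np.array([lookup[a] for a in atoms], dtype=float)


def extract_features(
    reference: pd.DataFrame,
    trajectory: pd.DataFrame,
    selection: AtomSelection,
    frame_dt_ps: float = 2.0,
    superpose: bool = False,
) -> pd.DataFrame:
    """Compute the standard feature table from coordinate tables.

    ``reference`` is a single-frame table; ``trajectory`` a multi-frame
    one.  ``rmsd_pair`` is taken over the union of the guide and target
    selections.  Output columns match the synthetic generator, so every
    downstream stage is source agnostic.
    """
    pair_atoms = tuple(selection.guide_atoms) + tuple(
        a for a in selection.target_atoms if a not in selection.guide_atoms
    )
    ref_one = reference[reference["frame"] == reference["frame"].iloc[0]] if "frame" in reference else reference
    ref = {
        "guide": _frame_coords(ref_one, selection.guide_atoms),
        "target": _frame_coords(ref_one, selection.target_atoms),
        "pair": _frame_coords(ref_one, pair_atoms),
    }
    rows = []
    for k, (frame_id, frame_df) in enumerate(trajectory.groupby("frame", sort=True)):
        rows.append(
            {
                "time_ps": k * frame_dt_ps,
                "rmsd_pair_A": rmsd(_frame_coords(frame_df, pair_atoms), ref["pair"], superpose),
                "rmsd_guide_A": rmsd(
                    _frame_coords(frame_df, selection.guide_atoms), ref["guide"], superpose
                ),
                "rmsd_target_A": rmsd(
                    _frame_coords(frame_df, selection.target_atoms), ref["target"], superpose
                ),
                "zeta_guide_deg": dihedral(*_frame_coords(frame_df, selection.zeta_guide)),
                "zeta_target_deg": dihedral(*_frame_coords(frame_df, selection.zeta_target)),
            }
        )
    if not rows:
        raise ValueError("trajectory table contains no frames")
    return pd.DataFrame(rows)


def features_from_universe(
    universe,
    selection: AtomSelection,
    frame_dt_ps: float | None = None,
    superpose: bool = False,
):
    """Feature table from an MDAnalysis ``Universe`` (optional reader layer).

    Atom identifiers in ``selection`` are MDAnalysis selection strings,
    each of which must resolve to the expected atom count; the reference
    structure is the first trajectory frame.
    """
    def select(sel_strings, n_expected=None):
        groups = []
        for s in sel_strings:
            g = universe.select_atoms(s)
            if g.n_atoms == 0:
                raise ValueError(f"selection {s!r} matches no atoms")
            if n_expected == 1 and g.n_atoms != 1:
                raise ValueError(f"selection {s!r} must match exactly one atom")
            groups.append(g)
        return groups

    guide = select(selection.guide_atoms)
    target = select(selection.target_atoms)
    zg = select(selection.zeta_guide, n_expected=1)
    zt = select(selection.zeta_target, n_expected=1)

    def coords(groups):
        return np.concatenate([g.positions for g in groups], axis=0)

    universe.trajectory[0]
    ref_guide, ref_target = coords(guide).copy(), coords(target).copy()
    ref_pair = np.concatenate([ref_guide, ref_target], axis=0)
    if frame_dt_ps is None:
        frame_dt_ps = getattr(universe.trajectory, "dt", 1.0) or 1.0
    rows = []
    for k, _ in enumerate(universe.trajectory):
        g, t = coords(guide), coords(target)
        rows.append(
            {
                "time_ps": k * frame_dt_ps,
                "rmsd_pair_A": rmsd(np.concatenate([g, t]), ref_pair, superpose),
                "rmsd_guide_A": rmsd(g, ref_guide, superpose),
                "rmsd_target_A": rmsd(t, ref_target, superpose),
                "zeta_guide_deg": dihedral(*[a.positions[0] for a in zg]),
                "zeta_target_deg": dihedral(*[a.positions[0] for a in zt]),
            }
        )
    return pd.DataFrame(rows)
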