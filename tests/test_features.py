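"""Geometry: torsion angles, RMSD without superposition, feature extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pairswitch.features import (
    AtomSelection,
    DegenerateGeometryError,
    dihedral,
    extract_features,
    features_from_universe,
    rmsd,
)


def reference_torsion(p1, p2, p3, p4):
    """Independent oracle: projection construction (no plane normals).

    Projects the outer bonds onto the plane perpendicular to the central
    bond and measures the signed angle between the projections — a
    different derivation from the package's normal-vector formula.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p1 - p2, p3 - p2, p4 - p3
    b2u = b2 / np.linalg.norm(b2)
    v = b1 - np.dot(b1, b2u) * b2u
    w = b3 - np.dot(b3, b2u) * b2u
    x = np.dot(v, w)
    y = np.dot(np.cross(b2u, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def mdanalysis_torsion(p1, p2, p3, p4):
    """Second cross-check: MDAnalysis's routine (float32 internals)."""
    from MDAnalysis.lib.distances import calc_dihedrals

    args = [np.asarray([p], dtype=np.float64) for p in (p1, p2, p3, p4)]
    return float(np.degrees(calc_dihedrals(*args))[0])


def random_rigid_motion(rng):
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=rng).as_matrix()
    shift = rng.normal(scale=10.0, size=3)
    return lambda p: rot @ np.asarray(p) + shift


class TestDihedral:
    def test_planar_cis_is_zero(self):
        assert dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]) == pytest.approx(0.0)

    def test_planar_trans_is_180(self):
        angle = dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0])
        assert angle == pytest.approx(180.0)

    def test_matches_independent_reference_on_random_quadruples(self, rng):
        for _ in range(50):
            pts = rng.normal(scale=3.0, size=(4, 3))
            assert dihedral(*pts) == pytest.approx(
                reference_torsion(*pts), abs=1e-6
            )

    def test_sign_convention_matches_mdanalysis(self, rng):
        for _ in range(10):
            pts = rng.normal(scale=3.0, size=(4, 3))
            assert dihedral(*pts) == pytest.approx(
                mdanalysis_torsion(*pts), abs=1e-3
            )

    def test_invariant_under_rigid_motion(self, rng):
        for _ in range(20):
            pts = rng.normal(scale=3.0, size=(4, 3))
            move = random_rigid_motion(rng)
            moved = [move(p) for p in pts]
            assert dihedral(*moved) == pytest.approx(dihedral(*pts), abs=1e-6)

    def test_reversal_symmetry(self, rng):
        for _ in range(20):
            p = rng.normal(size=(4, 3))
            assert dihedral(p[3], p[2], p[1], p[0]) == pytest.approx(
                dihedral(*p), abs=1e-9
            )

    def test_collinear_triple_raises(self):
        with pytest.raises(DegenerateGeometryError):
            dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])

    def test_coincident_points_raise(self):
        with pytest.raises(DegenerateGeometryError):
            dihedral([0, 0, 0], [0, 0, 0], [1, 1, 0], [2, 0, 0])

    def test_range_is_half_open(self, rng):
        for _ in range(200):
            pts = rng.normal(size=(4, 3))
            try:
                angle = dihedral(*pts)
            except DegenerateGeometryError:
                continue
            assert -180.0 < angle <= 180.0


class TestRmsd:
    def test_identity_is_zero(self, rng):
        coords = rng.normal(size=(5, 3))
        assert rmsd(coords, coords) == 0.0

    def test_single_displaced_atom(self):
        assert rmsd([[1.0, 0, 0]], [[0.0, 0, 0]]) == pytest.approx(1.0)

    def test_two_atom_closed_form(self):
        ref = np.zeros((2, 3))
        coords = np.array([[3.0, 0, 0], [0, 4.0, 0]])
        assert rmsd(coords, ref) == pytest.approx(np.sqrt((9 + 16) / 2))

    def test_no_superposition_by_default(self):
        # a pure translation must NOT be removed
        ref = np.arange(12.0).reshape(4, 3)
        assert rmsd(ref + 1.0, ref) == pytest.approx(np.sqrt(3))
        assert rmsd(ref + 1.0, ref, superpose=True) == pytest.approx(0.0, abs=1e-9)

    def test_mismatched_counts_raise(self):
        with pytest.raises(ValueError):
            rmsd(np.zeros((3, 3)), np.zeros((4, 3)))

    @given(st.integers(1, 6), st.integers(1, 6), st.integers(0, 2**32 - 1))
    def test_pair_decomposition_identity(self, n_guide, n_target, seed):
        # n_pair * rmsd_pair^2 == n_g * rmsd_g^2 + n_t * rmsd_t^2
        r = np.random.default_rng(seed)
        ref_g, ref_t = r.normal(size=(n_guide, 3)), r.normal(size=(n_target, 3))
        g, t = r.normal(size=(n_guide, 3)), r.normal(size=(n_target, 3))
        lhs = (n_guide + n_target) * rmsd(
            np.vstack([g, t]), np.vstack([ref_g, ref_t])
        ) ** 2
        rhs = n_guide * rmsd(g, ref_g) ** 2 + n_target * rmsd(t, ref_t) ** 2
        assert lhs == pytest.approx(rhs, rel=1e-12)


def _coordinate_table(frames: dict[int, dict[str, tuple]]) -> pd.DataFrame:
    rows = [
        {"frame": f, "atom": a, "x": p[0], "y": p[1], "z": p[2]}
        for f, atoms in frames.items()
        for a, p in atoms.items()
    ]
    return pd.DataFrame(rows)


SELECTION = AtomSelection(
    guide_atoms=("g1", "g2"),
    target_atoms=("t1", "t2"),
    zeta_guide=("g1", "g2", "t1", "t2"),
    zeta_target=("t1", "t2", "g1", "g2"),
)


class TestExtractFeatures:
    def reference_frame(self):
        return {
            "g1": (0.0, 1.0, 0.0),
            "g2": (0.0, 0.0, 0.0),
            "t1": (1.0, 0.0, 0.0),
            "t2": (1.0, 1.0, 0.0),
        }

    def test_frame_equal_to_reference_gives_zero_rmsd(self):
        ref = _coordinate_table({0: self.reference_frame()})
        traj = _coordinate_table({0: self.reference_frame()})
        out = extract_features(ref, traj, SELECTION)
        assert out.loc[0, ["rmsd_pair_A", "rmsd_guide_A", "rmsd_target_A"]].tolist() == [
            0.0,
            0.0,
            0.0,
        ]

    def test_hand_placed_displacement(self):
        ref_atoms = self.reference_frame()
        moved = dict(ref_atoms)
        moved["t1"] = (1.0, 0.0, 2.0)  # one target atom moved 2 A in z
        out = extract_features(
            _coordinate_table({0: ref_atoms}), _coordinate_table({0: moved}), SELECTION
        )
        assert out.loc[0, "rmsd_target_A"] == pytest.approx(np.sqrt(4 / 2))
        assert out.loc[0, "rmsd_guide_A"] == 0.0
        assert out.loc[0, "rmsd_pair_A"] == pytest.approx(np.sqrt(4 / 4))

    def test_rotated_backbone_reports_known_torsion(self):
        theta = np.radians(60.0)
        atoms = self.reference_frame()
        atoms["t2"] = (1.0, np.cos(theta), np.sin(theta))
        out = extract_features(
            _coordinate_table({0: atoms}), _coordinate_table({0: atoms}), SELECTION
        )
        expected = reference_torsion(
            atoms["g1"], atoms["g2"], atoms["t1"], atoms["t2"]
        )
        assert abs(out.loc[0, "zeta_guide_deg"]) == pytest.approx(60.0, abs=1e-6)
        assert out.loc[0, "zeta_guide_deg"] == pytest.approx(expected, abs=1e-6)

    def test_missing_atoms_are_named(self):
        ref = _coordinate_table({0: self.reference_frame()})
        bad = _coordinate_table({0: {"g1": (0, 1, 0)}})
        with pytest.raises(ValueError, match="g2"):
            extract_features(ref, bad, SELECTION)

    def test_time_axis_uses_frame_interval(self):
        atoms = self.reference_frame()
        table = _coordinate_table({0: atoms, 1: atoms, 2: atoms})
        out = extract_features(
            _coordinate_table({0: atoms}), table, SELECTION, frame_dt_ps=2.0
        )
        assert out["time_ps"].tolist() == [0.0, 2.0, 4.0]


class TestMDAnalysisReader:
    def test_matches_table_route(self):
        mda = pytest.importorskip("MDAnalysis")
        atoms = {
            "g1": (0.0, 1.0, 0.0),
            "g2": (0.0, 0.0, 0.0),
            "t1": (1.0, 0.0, 0.0),
            "t2": (1.0, 1.0, 0.25),
        }
        moved = {k: (v[0], v[1], v[2] + (0.5 if k == "t1" else 0.0)) for k, v in atoms.items()}
        u = mda.Universe.empty(4, trajectory=True)
        u.add_TopologyAttr("names", list(atoms))
        coords = np.array(
            [[atoms[a] for a in atoms], [moved[a] for a in atoms]], dtype=np.float64
        )
        u.load_new(coords, order="fac")
        sel = AtomSelection(
            guide_atoms=("name g1", "name g2"),
            target_atoms=("name t1", "name t2"),
            zeta_guide=("name g1", "name g2", "name t1", "name t2"),
            zeta_target=("name t1", "name t2", "name g1", "name g2"),
        )
        via_universe = features_from_universe(u, sel, frame_dt_ps=2.0)
        via_table = extract_features(
            _coordinate_table({0: atoms}),
            _coordinate_table({0: atoms, 1: moved}),
            SELECTION,
            frame_dt_ps=2.0,
        )
        for col in via_table.columns:
            assert via_universe[col].to_numpy() == pytest.approx(
                via_table[col].to_numpy(), abs=1e-5
            )
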