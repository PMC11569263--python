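"""Conformational descriptors: angles, distances, areas, torsions, RMSD."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation
from scipy.stats import circmean

from oraikit import (
    ChannelSpec,
    build_channel,
    dihedral,
    kabsch_rmsd,
    moiety_distance,
    pooled_histogram,
    rotation_angle,
    series_over_trajectory,
    triangle_area,
)
from oraikit.trajectory_model import Frame, SelectionSpec


def geometry_frame(ca, cg, pore_atoms):
    """Frame with a residue-181 CA/CG pair plus pore-defining atoms (80-110)."""
    n_pore = len(pore_atoms)
    return Frame(
        atom_names=["CA"] * n_pore + ["CA", "CG"],
        elements=["C"] * (n_pore + 2),
        residue_names=["ALA"] * (n_pore + 2),
        residue_numbers=list(range(80, 80 + n_pore)) + [181, 181],
        subunit_ids=["A"] * (n_pore + 2),
        positions=np.vstack([pore_atoms, ca, cg]),
    )


PORE_RING = [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0]]  # centre = origin


# -------------------------------------------------------------- rotation angle


def test_sidechain_toward_pore_is_zero_degrees():
    f = geometry_frame(ca=[10, 0, 5], cg=[8, 0, 6], pore_atoms=PORE_RING)
    assert rotation_angle(f, 181, "A") == pytest.approx(0.0, abs=1e-9)


def test_tangential_sidechain_is_ninety_degrees():
    f = geometry_frame(ca=[10, 0, 5], cg=[10, 2, 5], pore_atoms=PORE_RING)
    assert rotation_angle(f, 181, "A") == pytest.approx(90.0, abs=1e-9)


def test_sidechain_away_from_pore_is_180_degrees():
    f = geometry_frame(ca=[10, 0, 5], cg=[12, 0, 5], pore_atoms=PORE_RING)
    assert rotation_angle(f, 181, "A") == pytest.approx(180.0, abs=1e-9)


def test_angle_invariant_under_z_rotation_and_xy_translation(rng):
    f = geometry_frame(ca=[10, 0, 5], cg=[8.5, 1.2, 6], pore_atoms=PORE_RING)
    base = rotation_angle(f, 181, "A")
    ang = rng.uniform(0, 2 * np.pi)
    R = np.array([[np.cos(ang), -np.sin(ang), 0],
                  [np.sin(ang), np.cos(ang), 0],
                  [0, 0, 1.0]])
    moved = f.with_positions(f.positions @ R.T + np.array([3.7, -2.2, 9.0]))
    assert rotation_angle(moved, 181, "A") == pytest.approx(base, abs=1e-9)


def test_degenerate_projection_flagged_nan():
    # CG straight above CA: zero-length xy projection
    f = geometry_frame(ca=[10, 0, 5], cg=[10, 0, 6.5], pore_atoms=PORE_RING)
    assert np.isnan(rotation_angle(f, 181, "A"))


# ------------------------------------------------------------ moiety distance


def test_single_moiety_atom_345_triangle():
    f = geometry_frame(ca=[9, 9, 9], cg=[3, 4, 10], pore_atoms=PORE_RING)
    assert moiety_distance(f, {"CG"}, 181, "A") == pytest.approx(5.0, abs=1e-12)


def test_two_atom_moiety_center():
    f = Frame(
        atom_names=["CA"] * 4 + ["NH1", "NH2"],
        elements=["C"] * 4 + ["N", "N"],
        residue_names=["ALA"] * 4 + ["ARG", "ARG"],
        residue_numbers=[80, 81, 82, 83, 181, 181],
        subunit_ids=["A"] * 6,
        positions=np.array(PORE_RING + [[3, 4, 0], [5, 4, 2]], dtype=float),
    )
    assert moiety_distance(f, {"NH1", "NH2"}, 181, "A") == pytest.approx(
        np.sqrt(32), abs=1e-12
    )


def test_moiety_on_axis_is_zero():
    f = geometry_frame(ca=[9, 9, 9], cg=[0, 0, 12], pore_atoms=PORE_RING)
    assert moiety_distance(f, {"CG"}, 181, "A") == 0.0


# -------------------------------------------------------------- triangle area


@pytest.mark.parametrize(
    "points,expected",
    [
        (([0, 0, 0], [3, 0, 0], [0, 4, 0]), 6.0),
        (([0, 0, 0], [1, 0, 0], [2, 0, 0]), 0.0),
        (([0, 0, 0], [1, 0, 0], [0, 1, 1]), np.sqrt(2) / 2),
    ],
)
def test_triangle_area_closed_forms(points, expected):
    a, b, c = (np.asarray(p, dtype=float) for p in points)
    f = Frame(
        atom_names=["CA"] * 3,
        elements=["C"] * 3,
        residue_names=["ALA"] * 3,
        residue_numbers=[143, 177, 253],
        subunit_ids=["A"] * 3,
        positions=np.vstack([a, b, c]),
    )
    assert triangle_area(f, (143, 177, 253), "CA", "A") == pytest.approx(
        expected, abs=1e-15
    )


def test_triangle_area_rigid_invariance_and_scaling(rng):
    pts = rng.normal(size=(3, 3)) * 5
    f = Frame(
        atom_names=["CA"] * 3, elements=["C"] * 3, residue_names=["ALA"] * 3,
        residue_numbers=[143, 177, 253], subunit_ids=["A"] * 3, positions=pts,
    )
    base = triangle_area(f)
    R = Rotation.random(random_state=3).as_matrix()
    moved = f.with_positions(pts @ R.T + rng.normal(size=3))
    assert triangle_area(moved) == pytest.approx(base, rel=1e-12)
    scaled = f.with_positions(pts * 2.5)
    assert triangle_area(scaled) == pytest.approx(base * 2.5**2, rel=1e-12)


# ------------------------------------------------------------------ dihedrals


def test_dihedral_cis_trans_and_quarter_twist():
    assert dihedral([1, 1, 0], [1, 0, 0], [-1, 0, 0], [-1, 1, 0]) == pytest.approx(
        0.0, abs=1e-12
    )
    assert abs(
        dihedral([1, 1, 0], [1, 0, 0], [-1, 0, 0], [-1, -1, 0])
    ) == pytest.approx(180.0, abs=1e-12)
    # right-handed quarter twist (sign convention cross-checked against
    # MDAnalysis calc_dihedrals on the same coordinates)
    assert dihedral([1, 1, 0], [1, 0, 0], [-1, 0, 0], [-1, 0, -1]) == pytest.approx(
        90.0, abs=1e-12
    )
    assert dihedral([1, 1, 0], [1, 0, 0], [-1, 0, 0], [-1, 0, 1]) == pytest.approx(
        -90.0, abs=1e-12
    )


def test_dihedral_degenerate_is_nan():
    assert np.isnan(dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]))


# ----------------------------------------------------------------- Kabsch RMSD


def _ten_atom_frames(rng, displace=None):
    pts = rng.normal(size=(10, 3)) * 4
    ref = Frame(
        atom_names=["CA"] * 10, elements=["C"] * 10, residue_names=["ALA"] * 10,
        residue_numbers=np.arange(80, 90), subunit_ids=["A"] * 10, positions=pts,
    )
    mob_pts = pts.copy()
    if displace is not None:
        mob_pts[0] += displace
    mob = ref.with_positions(mob_pts)
    return mob, ref


FIT = SelectionSpec((80, 89), {"CA"}, "all")


def test_rmsd_of_reference_vs_itself_is_zero(rng):
    mob, ref = _ten_atom_frames(rng)
    assert kabsch_rmsd(mob, ref, FIT) == pytest.approx(0.0, abs=1e-12)


def test_rigid_transform_recovered_to_numerical_zero(rng):
    mob, ref = _ten_atom_frames(rng)
    R = Rotation.from_rotvec(np.radians(37) * np.array([0.6, 0.64, 0.48]))
    moved = mob.with_positions(R.apply(mob.positions) + np.array([5, -3, 2.0]))
    assert kabsch_rmsd(moved, ref, FIT) < 1e-8


def test_kabsch_matches_direct_numerical_optimizer(rng):
    """Closed-form superposition vs brute-force optimisation over rigid moves."""
    mob, ref = _ten_atom_frames(rng, displace=np.array([1.0, 0, 0]))
    analytic = kabsch_rmsd(mob, ref, FIT)

    m = mob.positions
    r = ref.positions

    def objective(params):
        rot = Rotation.from_rotvec(params[:3])
        moved = rot.apply(m) + params[3:]
        return np.sqrt(np.mean(np.sum((moved - r) ** 2, axis=1)))

    best = min(
        (
            minimize(objective, x0, method="Nelder-Mead",
                     options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 20000})
            for x0 in [np.zeros(6), np.array([0.1, -0.1, 0.2, 0.5, 0.5, -0.5])]
        ),
        key=lambda res: res.fun,
    )
    assert analytic == pytest.approx(best.fun, abs=1e-6)


def test_kabsch_symmetric_and_fitted_below_unfitted(rng):
    for _ in range(10):
        mob, ref = _ten_atom_frames(rng, displace=rng.normal(size=3))
        extra = Rotation.from_rotvec(rng.normal(size=3) * 0.3)
        mob = mob.with_positions(extra.apply(mob.positions) + rng.normal(size=3))
        fwd = kabsch_rmsd(mob, ref, FIT)
        rev = kabsch_rmsd(ref, mob, FIT)
        unfitted = np.sqrt(
            np.mean(np.sum((mob.positions - ref.positions) ** 2, axis=1))
        )
        assert fwd == pytest.approx(rev, abs=1e-9)
        assert fwd <= unfitted + 1e-12


def test_kabsch_rejects_too_few_atoms(rng):
    mob, ref = _ten_atom_frames(rng)
    with pytest.raises(ValueError, match="3 atoms"):
        kabsch_rmsd(mob, ref, SelectionSpec((80, 81), {"CA"}, "all"))


# --------------------------------------------------------------------- series


def test_constant_trajectory_gives_constant_series():
    spec = ChannelSpec(orientation_kappa=0.0, n_frames=4, seed=0)
    trajs, _ = build_channel(spec)
    series = series_over_trajectory(
        trajs, lambda f, s: rotation_angle(f, 181, s), unit="deg"
    )
    assert series.values.shape == (4, 6)
    assert np.ptp(series.values) < 1e-9


def test_pooled_histogram_frequencies_sum_to_one():
    spec = ChannelSpec(n_frames=10, seed=4)
    trajs, _ = build_channel(spec)
    series = series_over_trajectory(trajs, lambda f, s: rotation_angle(f, 181, s))
    _, freq = pooled_histogram(series, bin_width=5.0)
    assert freq.sum() == pytest.approx(1.0, abs=1e-9)


def test_von_mises_orientation_recovery():
    """Planted von Mises(60 deg, kappa=8) orientations: circular mean within 2 deg."""
    spec = ChannelSpec(
        orientation_mu_deg=60.0, orientation_kappa=8.0, n_frames=84, seed=13
    )
    trajs, truth = build_channel(spec)
    series = series_over_trajectory(trajs, lambda f, s: rotation_angle(f, 181, s))
    vals = series.pooled()
    assert vals.size == 84 * 6
    assert np.all((vals >= 0.0) & (vals <= 180.0))
    mean = circmean(vals, high=180.0, low=-180.0)
    assert abs(mean - 60.0) < 2.0
    # computed angles equal |planted deviation| exactly (up to fold + fp noise)
    assert np.allclose(
        np.sort(vals), np.sort(np.abs(truth["orientation_deg"].reshape(-1))),
        atol=1e-9,
    )
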