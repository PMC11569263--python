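"""Structure I/O, atom selection and table round trips."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oraikit import (
    ChannelSpec,
    Frame,
    ScalarSeries,
    SelectionSpec,
    build_channel,
    read_structure,
    read_table,
    select_atoms,
    write_structure,
    write_table,
)
from oraikit.hydration import AxialProfile
from oraikit.trajectory_model import (
    SelectionError,
    StructureParseError,
    Trajectory,
)

from conftest import point_frame


# ---------------------------------------------------------------- structure IO


def test_single_model_pdb_roundtrip(tmp_path):
    frame = point_frame(np.arange(30).reshape(10, 3) * 0.5)
    write_structure(frame, tmp_path / "one.pdb")
    traj = read_structure(tmp_path / "one.pdb")
    assert len(traj) == 1
    assert traj.frames[0].n_atoms == 10


def test_multi_model_pdb_keeps_frame_count_and_ordering(tmp_path):
    spec = ChannelSpec(n_frames=3, seed=3)
    (traj,), _ = build_channel(spec)
    write_structure(traj, tmp_path / "t.pdb")
    back = read_structure(tmp_path / "t.pdb")
    assert len(back) == 3
    for f_in, f_out in zip(traj.frames, back.frames):
        assert np.array_equal(f_in.atom_names, f_out.atom_names)
        assert np.array_equal(f_in.residue_numbers, f_out.residue_numbers)
        assert np.array_equal(f_in.subunit_ids, f_out.subunit_ids)


def test_pdb_coordinates_roundtrip_within_format_precision(tmp_path):
    """Fixed-width PDB stores 3 decimals: 1e-3 Angstrom round-trip bound."""
    spec = ChannelSpec(pore_water_density=0.01, n_frames=2, seed=11)
    (traj,), _ = build_channel(spec)
    write_structure(traj, tmp_path / "t.pdb")
    back = read_structure(tmp_path / "t.pdb")
    for f_in, f_out in zip(traj.frames, back.frames):
        assert np.abs(f_in.positions - f_out.positions).max() <= 1e-3 + 1e-12


def test_xyz_roundtrip_of_coordinates(tmp_path):
    path = tmp_path / "w.xyz"
    path.write_text("3\nframe 0\nC 0.0 0.0 0.0\nO 1.0 2.0 3.0\nN -1.5 0.25 9.0\n")
    traj = read_structure(path)
    assert traj.frames[0].n_atoms == 3
    assert np.allclose(traj.frames[0].positions[2], [-1.5, 0.25, 9.0])
    assert list(traj.frames[0].elements) == ["C", "O", "N"]


def test_unknown_element_is_named_in_error(tmp_path):
    path = tmp_path / "bad.xyz"
    path.write_text("1\nhuh\nXq 0 0 0\n")
    with pytest.raises(StructureParseError, match="Xq"):
        read_structure(path)


def test_malformed_xyz_reports_line(tmp_path):
    path = tmp_path / "bad.xyz"
    path.write_text("2\ncomment\nC 0 0 0\nO nope nope nope\n")
    with pytest.raises(StructureParseError, match=":4"):
        read_structure(path)


def test_missing_file_raises():
    with pytest.raises(FileNotFoundError):
        read_structure("/nonexistent/file.pdb")


def test_trajectory_rejects_mismatched_frames():
    f1 = point_frame([[0, 0, 0]])
    f2 = point_frame([[0, 0, 0], [1, 1, 1]])
    f2.time = 1.0
    with pytest.raises(ValueError, match="atom count"):
        Trajectory(frames=[f1, f2])


def test_trajectory_rejects_nonincreasing_times():
    f1 = point_frame([[0, 0, 0]])
    f2 = point_frame([[1, 0, 0]])  # same default time 0.0
    with pytest.raises(ValueError, match="strictly increasing"):
        Trajectory(frames=[f1, f2])


# ------------------------------------------------------------------ selections


def test_tm1_calpha_selection_on_hexamer(dry_channel):
    frame, _ = dry_channel
    sel = select_atoms(frame, SelectionSpec((80, 110), {"CA"}, "all"))
    assert len(sel) == 31 * 6


def test_single_atom_selection(dry_channel):
    frame, _ = dry_channel
    sel = select_atoms(frame, SelectionSpec((181, 181), {"CG"}, {"A"}))
    assert len(sel) == 1
    assert sel[0].atom_name == "CG" and sel[0].residue_number == 181


def test_empty_selection_raises_with_spec_named(dry_channel):
    frame, _ = dry_channel
    with pytest.raises(SelectionError, match="999"):
        select_atoms(frame, SelectionSpec((999, 999), {"CA"}, "all"))


def test_selection_order_stable_and_idempotent(dry_channel):
    frame, _ = dry_channel
    spec = SelectionSpec((120, 150), {"CA"}, "all")
    idx = spec.indices(frame)
    assert np.array_equal(idx, np.sort(idx))
    assert np.array_equal(idx, spec.indices(frame))


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    lo1=st.integers(80, 100),
    len1=st.integers(0, 9),
    gap=st.integers(2, 20),
    len2=st.integers(0, 9),
)
def test_union_of_disjoint_ranges_equals_range_union(lo1, len1, gap, len2):
    """Selecting two disjoint residue ranges = union of the two selections."""
    rng = np.random.default_rng(0)
    frame = point_frame(
        rng.normal(size=(200, 3)), residue_numbers=np.arange(60, 260)
    )
    hi1 = lo1 + len1
    lo2, hi2 = hi1 + gap, hi1 + gap + len2
    a = set(SelectionSpec((lo1, hi1)).mask(frame).nonzero()[0])
    b = set(SelectionSpec((lo2, hi2)).mask(frame).nonzero()[0])
    both = set(SelectionSpec((lo1, hi2)).mask(frame).nonzero()[0])
    # the covering range picks up the gap residues too; removing them leaves a|b
    gap_idx = set(SelectionSpec((hi1 + 1, lo2 - 1)).mask(frame).nonzero()[0])
    assert both - gap_idx == a | b


def test_atom_record_invariants():
    with pytest.raises(ValueError):
        Frame(
            atom_names=["CA"], elements=["C"], residue_names=["ALA"],
            residue_numbers=[1], subunit_ids=["A"],
            positions=np.array([[np.inf, 0, 0]]),
        )
    with pytest.raises(ValueError):
        SelectionSpec((10, 5))


# ---------------------------------------------------------------------- tables


def test_scalar_series_csv_shape(tmp_path):
    series = ScalarSeries(
        times=[0.0, 1.0],
        subunit_ids=list("ABCDEF"),
        values=np.arange(12, dtype=float).reshape(2, 6),
        unit="deg",
    )
    out = tmp_path / "s.csv"
    write_table(series, out, "csv")
    lines = out.read_text().strip().splitlines()
    assert len(lines) == 3  # header + 2 rows
    assert len(lines[0].split(",")) == 7
    assert "deg" in lines[0]


def test_scalar_series_json_roundtrip(tmp_path):
    series = ScalarSeries(
        times=[0.0, 2.5], subunit_ids=["A", "B"],
        values=[[1.0, 2.0], [3.0, 4.0]], unit="A",
    )
    out = tmp_path / "s.json"
    write_table(series, out, "json")
    back = read_table(out)
    assert isinstance(back, ScalarSeries)
    assert np.array_equal(back.values, series.values)
    assert np.array_equal(back.times, series.times)
    assert back.unit == "A"


def test_axial_profile_json_consistent_lengths(tmp_path):
    prof = AxialProfile(
        bin_edges=np.arange(0.0, 6.0),
        per_replica=np.ones((3, 5)),
        mean=np.ones(5),
        sd_of_mean=np.zeros(5),
    )
    out = tmp_path / "p.json"
    write_table(prof, out, "json")
    d = json.loads(out.read_text())
    assert len(d["mean"]) == len(d["bin_edges_A"]) - 1 == len(d["sd_of_mean"])
    back = read_table(out)
    assert np.array_equal(back.per_replica, prof.per_replica)
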