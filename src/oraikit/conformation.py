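"""Side-chain and helix conformational descriptors.

Covers the geometric observables used to characterise how substitutions at
the TM3/TM4-interface reorganise the channel: the membrane-plane rotation
angle of a side chain relative to the pore direction, the in-plane distance
of a charged moiety from the pore centre, the Cα triangle spanned by the
residues framing the interface (143/177/253), generic torsions, and
Kabsch-superposed per-helix RMSD against a reference structure.

All descriptors operate on whole-molecule-imaged frames; no periodic-boundary
imaging is applied (see :func:`center_frame` for pre-centering).
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .trajectory_model import (
    Frame,
    PORE_SELECTION,
    ScalarSeries,
    SelectionSpec,
    Trajectory,
)
from .pore_geometry import pore_center

__all__ = [
    "MOIETY_ATOMS",
    "rotation_angle",
    "moiety_distance",
    "triangle_area",
    "dihedral",
    "kabsch_rmsd",
    "series_over_trajectory",
    "pooled_histogram",
    "center_frame",
]

# Charge-carrying moiety atom sets; the chemistry names the group, these are
# the conventional heavy-atom names implementing it.
MOIETY_ATOMS: dict[str, frozenset[str]] = {
    "LYS": frozenset({"NZ"}),
    "ARG": frozenset({"CZ", "NH1", "NH2", "NE"}),
    "GLU": frozenset({"CD", "OE1", "OE2"}),
    "ASP": frozenset({"CG", "OD1", "OD2"}),
}

_DEGENERATE = 1e-6  # Angstrom; below this a projected vector has no direction


def _atom_position(frame: Frame, residue: int, atom_name: str, subunit: str) -> np.ndarray:
    spec = SelectionSpec((residue, residue), frozenset({atom_name}), frozenset({subunit}))
    idx = spec.indices(frame)
    return frame.positions[idx[0]]


def rotation_angle(
    frame: Frame,
    residue: int = 181,
    subunit: str = "A",
    pore_selection: SelectionSpec = PORE_SELECTION,
) -> float:
    """Membrane-plane angle between the Cα→Cγ vector and the Cα→pore vector.

    Both vectors originate at the Cα and are projected onto the xy plane, so
    0° means the side chain points straight at the pore and 180° straight
    away from it.  Returns NaN when either projection is degenerate
    (< 1e-6 Å).
    """
    ca = _atom_position(frame, residue, "CA", subunit)
    cg = _atom_position(frame, residue, "CG", subunit)
    pc = pore_center(frame, pore_selection)
    u = (cg - ca)[:2]
    v = (pc - ca)[:2]
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < _DEGENERATE or nv < _DEGENERATE:
        return float("nan")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def moiety_distance(
    frame: Frame,
    atom_names: Sequence[str] | frozenset[str],
    residue: int = 181,
    subunit: str = "A",
    pore_selection: SelectionSpec = PORE_SELECTION,
) -> float:
    """xy-plane distance of a moiety's geometric centre from the pore centre.

    `atom_names` names the charge-carrying group (see :data:`MOIETY_ATOMS`,
    e.g. ``{"NZ"}`` for lysine's ammonium).
    """
    spec = SelectionSpec((residue, residue), frozenset(atom_names), frozenset({subunit}))
    idx = spec.indices(frame)
    center = frame.positions[idx].mean(axis=0)
    pc = pore_center(frame, pore_selection)
    return float(np.hypot(center[0] - pc[0], center[1] - pc[1]))


def triangle_area(
    frame: Frame,
    residues: tuple[int, int, int] = (143, 177, 253),
    atom_name: str = "CA",
    subunit: str = "A",
) -> float:
    """Area (Å²) of the 3-D triangle spanned by three atoms, ½|AB × AC|."""
    a, b, c = (_atom_position(frame, r, atom_name, subunit) for r in residues)
    return float(0.5 * np.linalg.norm(np.cross(b - a, c - a)))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed IUPAC torsion angle in degrees, range (−180, 180].

    0° is cis (p1 and p4 eclipsed), 180° trans, positive for a right-handed
    twist looking down p2→p3.  Degenerate geometry returns NaN.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if nb2 < _DEGENERATE or np.linalg.norm(n1) < _DEGENERATE**2 \
            or np.linalg.norm(n2) < _DEGENERATE**2:
        return float("nan")
    ang = np.degrees(np.arctan2(np.dot(np.cross(n1, n2), b2) / nb2, np.dot(n1, n2)))
    return 180.0 if ang <= -180.0 + 1e-12 else float(ang)


def kabsch_rmsd(
    mobile: Frame,
    reference: Frame,
    fit_selection: SelectionSpec,
    measure_selection: SelectionSpec | None = None,
) -> float:
    """RMSD (Å) after optimal rigid superposition of the fit selection.

    The rotation+translation minimising the fit-selection RMSD (Kabsch, no
    reflection) is applied to the mobile frame, then the RMSD is measured
    over `measure_selection` (defaults to the fit selection).  Selections
    must resolve to equal atom counts in identical order in both frames.
    """
    if measure_selection is None:
        measure_selection = fit_selection
    fit_m = mobile.positions[fit_selection.indices(mobile)]
    fit_r = reference.positions[fit_selection.indices(reference)]
    if fit_m.shape != fit_r.shape:
        raise ValueError(
            f"fit selections differ in atom count: {fit_m.shape[0]} vs {fit_r.shape[0]}"
        )
    if fit_m.shape[0] < 3:
        raise ValueError("need at least 3 atoms to fit a rigid transform")
    cm = fit_m.mean(axis=0)
    cr = fit_r.mean(axis=0)
    rot, _ = Rotation.align_vectors(fit_r - cr, fit_m - cm)
    meas_m = mobile.positions[measure_selection.indices(mobile)]
    meas_r = reference.positions[measure_selection.indices(reference)]
    if meas_m.shape != meas_r.shape:
        raise ValueError("measure selections differ in atom count")
    moved = rot.apply(meas_m - cm) + cr
    return float(np.sqrt(np.mean(np.sum((moved - meas_r) ** 2, axis=1))))


def series_over_trajectory(
    trajs: Sequence[Trajectory] | Trajectory,
    metric: Callable[[Frame, str], float],
    subunits: Sequence[str] | None = None,
    window: tuple[float, float] | None = None,
    unit: str = "",
    name: str = "",
) -> ScalarSeries:
    """Evaluate a per-subunit metric on every frame of one or more replicas.

    `metric(frame, subunit_id)` is any of the descriptors above wrapped in a
    closure, e.g. ``lambda f, s: rotation_angle(f, 181, s)``.  Replicas are
    concatenated along the frame axis (times repeat across replicas in the
    returned series when several replicas are given).
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    all_times: list[float] = []
    rows: list[list[float]] = []
    sub_ids: list[str] | None = list(subunits) if subunits is not None else None
    for traj in trajs:
        frames = traj.window(*window) if window else traj.frames
        if sub_ids is None:
            f0 = frames[0]
            sub_ids = list(dict.fromkeys(f0.subunit_ids[f0.protein_mask()]))
        for f in frames:
            rows.append([metric(f, s) for s in sub_ids])
            all_times.append(f.time)
    order = np.argsort(np.asarray(all_times), kind="stable")
    # times may repeat across replicas; ScalarSeries requires only shape agreement
    return ScalarSeries(
        times=np.asarray(all_times)[order],
        subunit_ids=sub_ids or [],
        values=np.asarray(rows)[order],
        unit=unit,
        name=name,
    )


def pooled_histogram(
    series: ScalarSeries, bin_width: float, range_: tuple[float, float] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Normalised histogram of all (frame, subunit) values of a series.

    Returns ``(bin_edges, frequency)`` with frequencies summing to 1.
    """
    vals = series.pooled()
    if vals.size == 0:
        raise ValueError("series has no finite values to histogram")
    if range_ is None:
        lo = np.floor(vals.min() / bin_width) * bin_width
        hi = np.ceil(vals.max() / bin_width) * bin_width
        hi = hi if hi > lo else lo + bin_width
    else:
        lo, hi = range_
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, edges = np.histogram(vals, bins=edges)
    return edges, counts / counts.sum()


def center_frame(frame: Frame, selection: SelectionSpec = PORE_SELECTION) -> Frame:
    """Translate a frame so the selection's geometric centre sits at origin."""
    idx = selection.indices(frame)
    shift = frame.positions[idx].mean(axis=0)
    return frame.with_positions(frame.positions - shift)
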