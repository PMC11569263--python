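"""Core structure/trajectory model, atom selections and tabular I/O.

The in-memory model is a structure-of-arrays :class:`Frame` (fast vectorised
analysis) with an :class:`AtomRecord` view for per-atom access.  Coordinate
conventions used throughout the package: the membrane plane is *xy*, the pore
axis is *z*, and the extracellular side lies at higher *z*.  Residue numbers
follow 1-based human Orai1 numbering and residue ranges are inclusive on both
ends.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AtomRecord",
    "Frame",
    "Trajectory",
    "SelectionSpec",
    "ScalarSeries",
    "VDW_RADII",
    "WATER_RESIDUE_NAMES",
    "WATER_OXYGEN_NAMES",
    "TM_SELECTIONS",
    "read_structure",
    "write_structure",
    "select_atoms",
    "write_table",
    "read_table",
]

# Bondi-type van der Waals radii in Angstrom.  The pore-cavity algorithm
# deducts these from centre-to-atom distances; values are overridable per call.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "NA": 2.27,
    "K": 2.75,
    "CA": 2.31,
    "MG": 1.73,
}

# Water recognition is a superset of common MD water naming conventions
# (TIP3P/SPC in GROMACS, CHARMM and PDB dialects).
WATER_RESIDUE_NAMES = frozenset({"HOH", "SOL", "TIP3", "WAT", "TIP", "SPC"})
WATER_OXYGEN_NAMES = frozenset({"O", "OW", "OH2"})


class SelectionError(ValueError):
    """Raised when a selection resolves to no atoms."""


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


@dataclass(frozen=True)
class AtomRecord:
    """A single atom: identity, topology labels and position (Angstrom)."""

    serial: int
    atom_name: str
    element: str
    residue_name: str
    residue_number: int
    subunit_id: str
    position: np.ndarray
    vdw_radius: float

    def __post_init__(self) -> None:
        if self.vdw_radius <= 0:
            raise ValueError(f"vdw_radius must be > 0, got {self.vdw_radius}")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be finite")


class Frame:
    """One trajectory snapshot as parallel per-atom arrays.

    Parameters
    ----------
    atom_names, elements, residue_names, subunit_ids : sequences of str
    residue_numbers : sequence of int
        1-based residue numbers.
    positions : (n_atoms, 3) float array, Angstrom.
    vdw_radii : (n_atoms,) float array, Angstrom; looked up from
        :data:`VDW_RADII` by element when omitted.
    time : float, ns.
    box : optional (3,) float array, Angstrom.
    """

    def __init__(
        self,
        atom_names: Sequence[str],
        elements: Sequence[str],
        residue_names: Sequence[str],
        residue_numbers: Sequence[int],
        subunit_ids: Sequence[str],
        positions: np.ndarray,
        vdw_radii: np.ndarray | None = None,
        time: float = 0.0,
        box: np.ndarray | None = None,
        serials: Sequence[int] | None = None,
    ) -> None:
        n = len(atom_names)
        self.atom_names = np.asarray(atom_names, dtype=object)
        self.elements = np.asarray([e.upper() for e in elements], dtype=object)
        self.residue_names = np.asarray(residue_names, dtype=object)
        self.residue_numbers = np.asarray(residue_numbers, dtype=np.int64)
        self.subunit_ids = np.asarray(subunit_ids, dtype=object)
        self.positions = np.asarray(positions, dtype=np.float64).reshape(n, 3)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("all atom positions must be finite")
        if vdw_radii is None:
            vdw_radii = np.array(
                [_vdw_for_element(e) for e in self.elements], dtype=np.float64
            )
        self.vdw_radii = np.asarray(vdw_radii, dtype=np.float64)
        if np.any(self.vdw_radii <= 0):
            raise ValueError("all vdW radii must be > 0")
        if time < 0:
            raise ValueError("frame time must be >= 0")
        self.time = float(time)
        self.box = None if box is None else np.asarray(box, dtype=np.float64)
        self.serials = (
            np.arange(1, n + 1, dtype=np.int64)
            if serials is None
            else np.asarray(serials, dtype=np.int64)
        )
        for arr in (
            self.atom_names,
            self.elements,
            self.residue_names,
            self.residue_numbers,
            self.subunit_ids,
            self.vdw_radii,
            self.serials,
        ):
            if len(arr) != n:
                raise ValueError("all per-atom arrays must share one length")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def atoms(self) -> list[AtomRecord]:
        """Materialise the per-atom record view (copy)."""
        return [
            AtomRecord(
                serial=int(self.serials[i]),
                atom_name=str(self.atom_names[i]),
                element=str(self.elements[i]),
                residue_name=str(self.residue_names[i]),
                residue_number=int(self.residue_numbers[i]),
                subunit_id=str(self.subunit_ids[i]),
                position=self.positions[i].copy(),
                vdw_radius=float(self.vdw_radii[i]),
            )
            for i in range(self.n_atoms)
        ]

    @classmethod
    def from_atoms(
        cls,
        atoms: Iterable[AtomRecord],
        time: float = 0.0,
        box: np.ndarray | None = None,
    ) -> "Frame":
        atoms = list(atoms)
        return cls(
            atom_names=[a.atom_name for a in atoms],
            elements=[a.element for a in atoms],
            residue_names=[a.residue_name for a in atoms],
            residue_numbers=[a.residue_number for a in atoms],
            subunit_ids=[a.subunit_id for a in atoms],
            positions=np.array([a.position for a in atoms], dtype=np.float64),
            vdw_radii=np.array([a.vdw_radius for a in atoms]),
            serials=[a.serial for a in atoms],
            time=time,
            box=box,
        )

    def water_oxygen_mask(self) -> np.ndarray:
        """Boolean mask of water oxygen atoms (one per water molecule)."""
        res = np.isin(self.residue_names, list(WATER_RESIDUE_NAMES))
        name = np.isin(self.atom_names, list(WATER_OXYGEN_NAMES))
        return res & name

    def water_oxygen_positions(self) -> np.ndarray:
        return self.positions[self.water_oxygen_mask()]

    def protein_mask(self) -> np.ndarray:
        return ~np.isin(self.residue_names, list(WATER_RESIDUE_NAMES))

    def with_positions(self, positions: np.ndarray, time: float | None = None) -> "Frame":
        """Copy of this frame with replaced coordinates (labels shared)."""
        f = Frame.__new__(Frame)
        f.__dict__.update(self.__dict__)
        f.positions = np.asarray(positions, dtype=np.float64).reshape(self.n_atoms, 3)
        if time is not None:
            f.time = float(time)
        return f


@dataclass
class Trajectory:
    """Ordered frames of one simulation replica.

    All frames must share atom count and ordering; times strictly increase.
    """

    frames: list[Frame]
    replica_id: int = 0

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory needs at least one frame")
        n0 = self.frames[0].n_atoms
        names0 = self.frames[0].atom_names
        for f in self.frames[1:]:
            if f.n_atoms != n0 or not np.array_equal(f.atom_names, names0):
                raise ValueError("all frames must share atom count and ordering")
        times = np.array([f.time for f in self.frames])
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def window(self, t0: float | None = None, t1: float | None = None) -> list[Frame]:
        """Frames with t0 <= time <= t1 (inclusive; None = open end)."""
        out = [
            f
            for f in self.frames
            if (t0 is None or f.time >= t0) and (t1 is None or f.time <= t1)
        ]
        if not out:
            raise ValueError(f"empty time window [{t0}, {t1}]")
        return out

    def last_ns(self, duration: float) -> tuple[float, float]:
        """Time window covering the final `duration` ns of the replica."""
        end = self.frames[-1].time
        return (end - duration, end)


@dataclass(frozen=True)
class SelectionSpec:
    """Atom selection: inclusive residue range AND atom names AND subunits."""

    residue_range: tuple[int, int]
    atom_names: frozenset[str] = frozenset({"CA"})
    subunits: frozenset[str] | str = "all"

    def __post_init__(self) -> None:
        lo, hi = self.residue_range
        if lo > hi:
            raise ValueError(f"residue range lo > hi: {self.residue_range}")
        object.__setattr__(self, "atom_names", frozenset(self.atom_names))
        if self.subunits != "all":
            object.__setattr__(self, "subunits", frozenset(self.subunits))

    def mask(self, frame: Frame) -> np.ndarray:
        lo, hi = self.residue_range
        m = (frame.residue_numbers >= lo) & (frame.residue_numbers <= hi)
        m &= np.isin(frame.atom_names, list(self.atom_names))
        if self.subunits != "all":
            m &= np.isin(frame.subunit_ids, list(self.subunits))
        return m

    def indices(self, frame: Frame) -> np.ndarray:
        idx = np.flatnonzero(self.mask(frame))
        if idx.size == 0:
            raise SelectionError(f"selection matched no atoms: {self}")
        return idx


# Named transmembrane-helix presets (human Orai1 numbering).  TM3 carries two
# presets: the display range 170-195 and the narrower 179-185 range used for
# superposition fitting.
TM_SELECTIONS: dict[str, SelectionSpec] = {
    "TM1": SelectionSpec((80, 110)),
    "TM2": SelectionSpec((120, 150)),
    "TM3": SelectionSpec((170, 195)),
    "TM3_FIT": SelectionSpec((179, 185)),
    "TM4": SelectionSpec((235, 262)),
}

#: Pore-defining selection: Calpha of TM1 residues 80-110, all subunits.
PORE_SELECTION = TM_SELECTIONS["TM1"]


def select_atoms(frame: Frame, spec: SelectionSpec) -> list[AtomRecord]:
    """Atoms matching `spec`, in frame order.  Raises on empty selection."""
    idx = spec.indices(frame)
    atoms = frame.atoms
    return [atoms[i] for i in idx]


@dataclass
class ScalarSeries:
    """Per-frame, per-subunit scalar descriptor (angle, distance, area, ...)."""

    times: np.ndarray
    subunit_ids: list[str]
    values: np.ndarray  # (n_frames, n_subunits)
    unit: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.times), len(self.subunit_ids)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.times)} times x {len(self.subunit_ids)} subunits"
            )

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"time_ns": self.times}
        for j, sid in enumerate(self.subunit_ids):
            label = f"{sid} ({self.unit})" if self.unit else str(sid)
            cols[label] = self.values[:, j]
        return pd.DataFrame(cols)

    def to_dict(self) -> dict:
        return {
            "kind": "scalar_series",
            "name": self.name,
            "unit": self.unit,
            "times_ns": self.times.tolist(),
            "subunit_ids": list(self.subunit_ids),
            "values": self.values.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalarSeries":
        return cls(
            times=np.asarray(d["times_ns"]),
            subunit_ids=list(d["subunit_ids"]),
            values=np.asarray(d["values"]),
            unit=d.get("unit", ""),
            name=d.get("name", ""),
        )

    def pooled(self, drop_nan: bool = True) -> np.ndarray:
        """All values flattened (frames x subunits), optionally NaN-free."""
        v = self.values.ravel()
        return v[~np.isnan(v)] if drop_nan else v


def _vdw_for_element(element: str) -> float:
    try:
        return VDW_RADII[element.upper()]
    except KeyError:
        raise StructureParseError(f"unknown element {element!r}: no vdW radius") from None


def _element_from_atom_name(atom_name: str) -> str:
    stripped = "".join(c for c in atom_name if c.isalpha())
    if not stripped:
        raise StructureParseError(f"cannot infer element from atom name {atom_name!r}")
    # Protein/water heavy atoms and hydrogens are all single-letter elements;
    # two-letter ions (NA, CL, MG, CA ions) must carry an element column.
    return stripped[0].upper()


def read_structure(
    path: str | Path,
    format: str | None = None,
    dt_ns: float = 1.0,
    replica_id: int = 0,
    vdw_radii: dict[str, float] | None = None,
) -> Trajectory:
    """Read a multi-frame coordinate file into a :class:`Trajectory`.

    PDB files are read through biotite (fixed-column v3.3; MODEL blocks define
    frames; the chain-ID column carries the subunit id).  XYZ files are plain
    per-frame element/x/y/z blocks and carry no residue metadata, so residue
    numbers fall back to the serial index.  Frame times are assigned as
    ``i * dt_ns`` because neither format stores time.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "xyz" if path.suffix.lower() == ".xyz" else "pdb"
    radii_table = dict(VDW_RADII)
    if vdw_radii:
        radii_table.update({k.upper(): v for k, v in vdw_radii.items()})

    if format == "pdb":
        frames = _read_pdb_frames(path, radii_table)
    elif format == "xyz":
        frames = _read_xyz_frames(path, radii_table)
    else:
        raise ValueError(f"unsupported format {format!r}")
    for i, f in enumerate(frames):
        f.time = i * dt_ns
    return Trajectory(frames=frames, replica_id=replica_id)


def _read_pdb_frames(path: Path, radii: dict[str, float]) -> list[Frame]:
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None)
    except Exception as exc:  # biotite reports the offending line
        raise StructureParseError(f"malformed PDB {path}: {exc}") from exc

    elements = []
    for el, name in zip(stack.element, stack.atom_name):
        el = str(el).strip()
        elements.append(el.upper() if el else _element_from_atom_name(str(name)))
    vdw = np.array(
        [
            radii[e] if e in radii else _missing_element(e)
            for e in elements
        ]
    )
    chains = [str(c) if str(c).strip() else "A" for c in stack.chain_id]
    frames = []
    n_models = stack.stack_depth()
    for m in range(n_models):
        frames.append(
            Frame(
                atom_names=[str(a) for a in stack.atom_name],
                elements=elements,
                residue_names=[str(r) for r in stack.res_name],
                residue_numbers=stack.res_id.astype(int),
                subunit_ids=chains,
                positions=np.asarray(stack.coord[m], dtype=np.float64),
                vdw_radii=vdw,
            )
        )
    return frames


def _missing_element(element: str) -> float:
    raise StructureParseError(f"unknown element {element!r}: no vdW radius")


def _read_xyz_frames(path: Path, radii: dict[str, float]) -> list[Frame]:
    frames: list[Frame] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError:
            raise StructureParseError(
                f"{path}:{i + 1}: expected atom count, got {lines[i]!r}"
            ) from None
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise StructureParseError(f"{path}:{i + 1}: truncated frame of {n} atoms")
        elements, coords = [], []
        for j, line in enumerate(block):
            parts = line.split()
            if len(parts) < 4:
                raise StructureParseError(f"{path}:{i + 3 + j}: malformed atom line {line!r}")
            el = parts[0].upper()
            if el not in radii:
                raise StructureParseError(f"unknown element {parts[0]!r}: no vdW radius")
            elements.append(el)
            try:
                coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
            except ValueError:
                raise StructureParseError(
                    f"{path}:{i + 3 + j}: malformed coordinates {line!r}"
                ) from None
        frames.append(
            Frame(
                atom_names=elements,
                elements=elements,
                residue_names=["UNK"] * n,
                residue_numbers=np.arange(1, n + 1),
                subunit_ids=["A"] * n,
                positions=np.array(coords),
                vdw_radii=np.array([radii[e] for e in elements]),
            )
        )
        i += 2 + n
    if not frames:
        raise StructureParseError(f"{path}: no frames found")
    return frames


def write_structure(traj: Trajectory | Frame, path: str | Path) -> None:
    """Write frames as a multi-MODEL PDB (fixed-column v3.3 via biotite)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    frames = traj.frames if isinstance(traj, Trajectory) else [traj]
    f0 = frames[0]
    n = f0.n_atoms
    arrays = []
    for f in frames:
        arr = struc.AtomArray(n)
        arr.coord = f.positions.astype(np.float32)
        arr.chain_id = f.subunit_ids.astype("U4")
        arr.res_id = f.residue_numbers
        arr.res_name = f.residue_names.astype("U5")
        arr.atom_name = f.atom_names.astype("U6")
        arr.element = f.elements.astype("U2")
        arr.hetero = np.isin(f.residue_names, list(WATER_RESIDUE_NAMES))
        arrays.append(arr)
    stack = struc.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def write_table(obj, path: str | Path, format: str = "csv") -> None:
    """Write a series/profile object to CSV or JSON.

    Any object exposing ``to_dataframe()`` (CSV) and ``to_dict()`` (JSON)
    is accepted: :class:`ScalarSeries`, hydration profiles, pore profiles.
    """
    path = Path(path)
    if format == "csv":
        obj.to_dataframe().to_csv(path, index=False)
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(obj.to_dict(), fh, indent=1)
    else:
        raise ValueError(f"unsupported table format {format!r}")


def read_table(path: str | Path, cls=None):
    """Read a JSON table written by :func:`write_table` back into its type.

    When `cls` is None the class is dispatched on the stored ``kind`` tag.
    """
    with open(path) as fh:
        d = json.load(fh)
    if cls is not None:
        return cls.from_dict(d)
    kind = d.get("kind")
    from . import hydration, pore_geometry

    dispatch = {
        "scalar_series": ScalarSeries,
        "axial_profile": hydration.AxialProfile,
        "pore_profile": pore_geometry.PoreProfile,
    }
    if kind not in dispatch:
        raise ValueError(f"cannot dispatch table kind {kind!r}")
    return dispatch[kind].from_dict(d)
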