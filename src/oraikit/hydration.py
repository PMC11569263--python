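"""Water-distribution analyses: axial cylinder histograms and shell counts.

Waters are represented by their oxygen atoms only.  Two selections mirror the
standard workflow for hexameric channels: waters inside a cylinder of a given
radius around the pore axis (10 Å for the conducting pore, 30 Å to take in
the peripheral "back pore" crevices), binned along z; and waters within a
spherical shell around a chosen side-chain anchor (6 Å around the Cα of
residue 181 for the TM3/TM4-interface).  All distance cutoffs are inclusive
(≤), fixed for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .trajectory_model import Frame, PORE_SELECTION, SelectionSpec, Trajectory
from .pore_geometry import pore_center

__all__ = [
    "AxialProfile",
    "ShellCountDistribution",
    "count_waters_within",
    "waters_in_cylinder",
    "axial_water_histogram",
    "shell_count_distribution",
]


@dataclass
class AxialProfile:
    """z-binned water counts (per bin, time-averaged) with replica stats."""

    bin_edges: np.ndarray  # relative to pore-centre z, Angstrom
    per_replica: np.ndarray  # (n_replicas, n_bins)
    mean: np.ndarray
    sd_of_mean: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=np.float64)
        self.per_replica = np.atleast_2d(np.asarray(self.per_replica, dtype=np.float64))
        if len(self.mean) != len(self.bin_edges) - 1:
            raise ValueError("mean length must be n_bins = len(bin_edges) - 1")
        if np.any(self.per_replica < 0) or np.any(np.asarray(self.sd_of_mean) < 0):
            raise ValueError("counts and SDs must be non-negative")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "z_center (A)": self.bin_centers,
                "waters_mean (count)": self.mean,
                "waters_sd_of_mean (count)": self.sd_of_mean,
            }
        )

    def to_dict(self) -> dict:
        return {
            "kind": "axial_profile",
            "bin_edges_A": self.bin_edges.tolist(),
            "per_replica": self.per_replica.tolist(),
            "mean": np.asarray(self.mean).tolist(),
            "sd_of_mean": np.asarray(self.sd_of_mean).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AxialProfile":
        return cls(
            bin_edges=np.asarray(d["bin_edges_A"]),
            per_replica=np.asarray(d["per_replica"]),
            mean=np.asarray(d["mean"]),
            sd_of_mean=np.asarray(d["sd_of_mean"]),
        )


@dataclass
class ShellCountDistribution:
    """Distribution of per-shell water counts pooled over frames/subunits."""

    counts: np.ndarray  # one integer per (frame, subunit) sample
    channel_mean: float  # mean over frames of the six-shell sum
    channel_means_per_replica: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)

    @property
    def support(self) -> np.ndarray:
        return np.unique(self.counts)

    @property
    def frequencies(self) -> np.ndarray:
        """Normalised frequency for each value of :attr:`support`."""
        _, c = np.unique(self.counts, return_counts=True)
        return c / self.counts.size

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"waters (count)": self.support, "frequency": self.frequencies}
        )

    def to_dict(self) -> dict:
        return {
            "kind": "shell_counts",
            "counts": self.counts.tolist(),
            "channel_mean": self.channel_mean,
            "channel_means_per_replica": np.asarray(
                self.channel_means_per_replica
            ).tolist(),
        }


def count_waters_within(frame: Frame, reference: np.ndarray, cutoff: float) -> int:
    """Number of water oxygens with ``||w - reference|| <= cutoff``."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    waters = frame.water_oxygen_positions()
    if waters.shape[0] == 0:
        return 0
    tree = cKDTree(waters)
    return len(tree.query_ball_point(np.asarray(reference, dtype=float), cutoff))


def waters_in_cylinder(
    frame: Frame,
    cylinder_radius: float,
    pore_selection: SelectionSpec = PORE_SELECTION,
) -> np.ndarray:
    """z-coordinates (relative to pore centre) of in-cylinder water oxygens.

    The cylinder is the vertical (z-aligned) cylinder through the frame's
    pore centre; membership is ``xy-distance <= radius`` (inclusive).
    """
    if cylinder_radius <= 0:
        raise ValueError("cylinder_radius must be > 0")
    pc = pore_center(frame, pore_selection)
    w = frame.water_oxygen_positions()
    if w.shape[0] == 0:
        return np.empty(0)
    dxy = np.hypot(w[:, 0] - pc[0], w[:, 1] - pc[1])
    return w[dxy <= cylinder_radius, 2] - pc[2]


def _as_replicas(trajs) -> list[Trajectory]:
    return [trajs] if isinstance(trajs, Trajectory) else list(trajs)


def axial_water_histogram(
    trajs: Sequence[Trajectory] | Trajectory,
    cylinder_radius: float = 10.0,
    dz: float = 1.0,
    window: tuple[float, float] | None = None,
    z_range: tuple[float, float] | None = None,
    pore_selection: SelectionSpec = PORE_SELECTION,
) -> AxialProfile:
    """Axial histogram of in-cylinder waters, averaged over time and replicas.

    With `z_range` None the bin range is taken from the data (snapped to the
    dz grid), so the histogram conserves the total in-cylinder count.  Bins
    are left-inclusive with the final bin closed.
    """
    if dz <= 0:
        raise ValueError("dz must be > 0")
    replicas = _as_replicas(trajs)
    if not replicas:
        raise ValueError("need at least one replica")
    per_rep_z = []
    for traj in replicas:
        frames = traj.window(*window) if window else traj.frames
        per_rep_z.append(
            [waters_in_cylinder(f, cylinder_radius, pore_selection) for f in frames]
        )
    if z_range is None:
        allz = np.concatenate([z for rep in per_rep_z for z in rep] or [np.zeros(0)])
        if allz.size == 0:
            lo, hi = -dz, dz
        else:
            lo = np.floor(allz.min() / dz) * dz
            hi = np.ceil(allz.max() / dz) * dz
            if hi <= lo:
                hi = lo + dz
    else:
        lo, hi = z_range
    edges = np.arange(lo, hi + 0.5 * dz, dz)
    per_replica = np.array(
        [
            np.mean([np.histogram(z, bins=edges)[0] for z in rep], axis=0)
            for rep in per_rep_z
        ]
    )
    mean = per_replica.mean(axis=0)
    n_rep = per_replica.shape[0]
    sd = (
        per_replica.std(axis=0, ddof=1) / np.sqrt(n_rep)
        if n_rep > 1
        else np.zeros_like(mean)
    )
    return AxialProfile(bin_edges=edges, per_replica=per_replica, mean=mean, sd_of_mean=sd)


def shell_count_distribution(
    trajs: Sequence[Trajectory] | Trajectory,
    residue: int = 181,
    atom_name: str = "CA",
    cutoff: float = 6.0,
    window: tuple[float, float] | None = None,
    subunits: Sequence[str] | str = "all",
) -> ShellCountDistribution:
    """Water counts in a sphere around one atom per subunit, pooled.

    For every frame and every requested subunit the number of water oxygens
    within `cutoff` of the ``residue``/``atom_name`` atom is collected.  The
    pooled samples give the count distribution; the per-channel mean sums the
    shells of all subunits per frame (a water inside two shells is counted in
    both) and averages over frames.
    """
    replicas = _as_replicas(trajs)
    samples: list[int] = []
    channel_means = []
    for traj in replicas:
        frames = traj.window(*window) if window else traj.frames
        f0 = frames[0]
        if subunits == "all":
            sub_ids = list(dict.fromkeys(f0.subunit_ids[f0.protein_mask()]))
        else:
            sub_ids = list(subunits)
        channel_sums = []
        for f in frames:
            per_sub = []
            for sid in sub_ids:
                spec = SelectionSpec((residue, residue), frozenset({atom_name}),
                                     frozenset({sid}))
                idx = spec.indices(f)  # raises if unresolvable
                ref = f.positions[idx].mean(axis=0)
                per_sub.append(count_waters_within(f, ref, cutoff))
            samples.extend(per_sub)
            channel_sums.append(sum(per_sub))
        channel_means.append(float(np.mean(channel_sums)))
    return ShellCountDistribution(
        counts=np.asarray(samples),
        channel_mean=float(np.mean(channel_means)),
        channel_means_per_replica=np.asarray(channel_means),
    )
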