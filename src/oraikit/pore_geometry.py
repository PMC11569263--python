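"""Pore-centre determination and slice-wise maximal-sphere pore radius.

The cavity profile follows the HOLE idea: at each position along the pore
axis, find the largest probe sphere that touches no protein atom, where the
clearance to atom *i* is ``||p - x_i|| - r_vdw,i``.  Instead of HOLE's
Monte-Carlo annealing the in-plane centre is found with a deterministic
Nelder-Mead search seeded from the previous slice, which makes profiles
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .trajectory_model import (
    Frame,
    PORE_SELECTION,
    SelectionSpec,
    Trajectory,
)

__all__ = ["PoreProfile", "pore_center", "slice_radius", "pore_radius_profile",
           "profile_over_trajectory"]

#: Axial slack added to each atom's vdW radius when collecting the atoms
#: that can constrain a slice (Angstrom).
PROBE_MARGIN = 3.0


@dataclass
class PoreProfile:
    """Pore radius vs axial position, with replica statistics.

    `z` is relative to the pore centre's z.  Slices with no nearby protein
    atoms are NaN (undefined, not blocked); negative radii mark sterically
    blocked slices and are reported as-is.
    """

    z: np.ndarray
    per_replica: np.ndarray  # (n_replicas, n_slices)
    mean: np.ndarray
    sd_of_mean: np.ndarray
    centers_xy: np.ndarray | None = None  # (n_slices, 2), last frame analysed

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=np.float64)
        self.per_replica = np.atleast_2d(np.asarray(self.per_replica, dtype=np.float64))
        if not np.all(np.diff(self.z) > 0):
            raise ValueError("z must be strictly ascending")

    @property
    def radius(self) -> np.ndarray:
        return self.mean

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "z (A)": self.z,
                "radius_mean (A)": self.mean,
                "radius_sd_of_mean (A)": self.sd_of_mean,
            }
        )

    def to_dict(self) -> dict:
        return {
            "kind": "pore_profile",
            "z_A": self.z.tolist(),
            "per_replica_A": self.per_replica.tolist(),
            "mean_A": self.mean.tolist(),
            "sd_of_mean_A": self.sd_of_mean.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PoreProfile":
        return cls(
            z=np.asarray(d["z_A"]),
            per_replica=np.asarray(d["per_replica_A"]),
            mean=np.asarray(d["mean_A"]),
            sd_of_mean=np.asarray(d["sd_of_mean_A"]),
        )


def pore_center(frame: Frame, pore_selection: SelectionSpec = PORE_SELECTION) -> np.ndarray:
    """Geometric centre of the pore-defining selection (default: Cα 80-110)."""
    idx = pore_selection.indices(frame)
    return frame.positions[idx].mean(axis=0)


def _clearance(cxy: np.ndarray, z: float, pos: np.ndarray, radii: np.ndarray) -> float:
    """Clearance of a probe centred at (cxy, z): min_i ||p - x_i|| - r_i."""
    d = np.sqrt(
        (pos[:, 0] - cxy[0]) ** 2 + (pos[:, 1] - cxy[1]) ** 2 + (pos[:, 2] - z) ** 2
    )
    return float(np.min(d - radii))


def slice_radius(
    positions: np.ndarray,
    radii: np.ndarray,
    z: float,
    center_xy: np.ndarray,
    optimize_center: bool = False,
    margin: float = PROBE_MARGIN,
) -> tuple[float, np.ndarray]:
    """Maximal probe radius at axial position `z`.

    Returns ``(radius, center_xy)``.  Atoms with ``|z_i - z| <= r_i + margin``
    constrain the slice; with none nearby the radius is NaN.  When
    `optimize_center` is set, the in-plane centre is refined by Nelder-Mead
    (xatol 1e-3 Å) starting from `center_xy`, and the better of seed and
    optimum is kept (the optimised radius can never drop below the fixed one).
    """
    near = np.abs(positions[:, 2] - z) <= radii + margin
    if not np.any(near):
        return float("nan"), np.asarray(center_xy, dtype=float)
    pos = positions[near]
    r = radii[near]
    c0 = np.asarray(center_xy, dtype=float)
    best = _clearance(c0, z, pos, r)
    if not optimize_center:
        return best, c0
    res = minimize(
        lambda c: -_clearance(c, z, pos, r),
        c0,
        method="Nelder-Mead",
        options={"xatol": 1e-3, "fatol": 1e-6, "maxiter": 400},
    )
    if -res.fun > best:
        return float(-res.fun), np.asarray(res.x, dtype=float)
    return best, c0


def pore_radius_profile(
    frame: Frame,
    z_range: tuple[float, float] = (-20.0, 20.0),
    dz: float = 1.0,
    protein_selection: SelectionSpec | None = None,
    optimize_center: bool = False,
    pore_selection: SelectionSpec = PORE_SELECTION,
    margin: float = PROBE_MARGIN,
) -> PoreProfile:
    """Slice-wise pore radius profile of one frame.

    `z_range` is relative to the pore centre's z.  `protein_selection`
    defaults to every non-water atom.  Slices walk from the centre outward so
    that each optimised centre seeds its neighbour.
    """
    if dz <= 0:
        raise ValueError("dz must be > 0")
    pc = pore_center(frame, pore_selection)
    if protein_selection is None:
        mask = frame.protein_mask()
        pos = frame.positions[mask]
        radii = frame.vdw_radii[mask]
    else:
        idx = protein_selection.indices(frame)
        pos = frame.positions[idx]
        radii = frame.vdw_radii[idx]

    z_rel = np.arange(z_range[0], z_range[1] + 0.5 * dz, dz)
    n = len(z_rel)
    radius = np.full(n, np.nan)
    centers = np.tile(pc[:2], (n, 1))
    # walk outward from the slice nearest the pore centre, seeding each
    # optimisation with its inner neighbour's centre
    order = np.argsort(np.abs(z_rel))
    seed_for: dict[int, np.ndarray] = {}
    for k in order:
        inner = seed_for.get(k, pc[:2])
        rad, c = slice_radius(
            pos, radii, pc[2] + z_rel[k], inner, optimize_center, margin
        )
        radius[k] = rad
        centers[k] = c
        for nb in (k - 1, k + 1):
            if 0 <= nb < n and nb not in seed_for:
                seed_for[nb] = c
    return PoreProfile(
        z=z_rel,
        per_replica=radius[None, :],
        mean=radius,
        sd_of_mean=np.zeros(n),
        centers_xy=centers,
    )


def profile_over_trajectory(
    trajs: Sequence[Trajectory] | Trajectory,
    window: tuple[float, float] | None = None,
    z_range: tuple[float, float] = (-20.0, 20.0),
    dz: float = 1.0,
    **kwargs,
) -> PoreProfile:
    """Time-averaged pore profile per replica, with cross-replica statistics.

    Each replica's frames inside `window` (inclusive, ns) are profiled and
    averaged; the profile reports the replica mean and the standard deviation
    of the mean (sample SD across replicas / sqrt(n_replicas)).
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    if not trajs:
        raise ValueError("need at least one replica")
    per_replica = []
    z = None
    centers = None
    for traj in trajs:
        frames = traj.window(*window) if window else traj.frames
        profs = [
            pore_radius_profile(f, z_range=z_range, dz=dz, **kwargs) for f in frames
        ]
        z = profs[0].z
        centers = profs[0].centers_xy
        per_replica.append(np.nanmean([p.mean for p in profs], axis=0))
    per_replica = np.asarray(per_replica)
    mean = per_replica.mean(axis=0)
    n_rep = per_replica.shape[0]
    if n_rep > 1:
        sd = per_replica.std(axis=0, ddof=1) / np.sqrt(n_rep)
    else:
        sd = np.zeros_like(mean)
    return PoreProfile(z=z, per_replica=per_replica, mean=mean, sd_of_mean=sd,
                       centers_xy=centers)
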