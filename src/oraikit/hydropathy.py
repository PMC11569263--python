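"""Sliding-window hydrophobicity profiles of protein sequences.

The default residue scale is Roseman's side-chain hydropathy scale
(free energy of transfer accounting for flanking peptide-bond effects;
positive = hydrophobic).  Profiles are unweighted centred moving averages
with an odd window; the conventional window range for locating membrane
helices is 9-25 residues.  Window centres keep 1-based sequence positions
and termini receive no score (no padding).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "HydropathyScale",
    "HydropathyProfile",
    "ROSEMAN",
    "hydropathy_profile",
    "profile_delta",
    "read_fasta",
]

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class HydropathyScale:
    """Per-residue hydropathy values; all 20 standard residues required."""

    name: str
    values: dict

    def __post_init__(self) -> None:
        missing = _STANDARD_AA - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues {sorted(missing)}")

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]


#: Roseman (1988) side-chain hydropathy scale (kcal/mol transfer free energy,
#: polar side chains attenuated by flanking peptide bonds).
ROSEMAN = HydropathyScale(
    "roseman",
    {
        "A": 0.39, "R": -3.95, "N": -1.91, "D": -3.81, "C": 0.25,
        "Q": -1.30, "E": -2.91, "G": 0.00, "H": -0.64, "I": 1.82,
        "L": 1.82, "K": -2.77, "M": 0.96, "F": 2.27, "P": 0.99,
        "S": -1.24, "T": -1.00, "W": 2.13, "Y": 1.47, "V": 1.30,
    },
)

SCALES = {"roseman": ROSEMAN}


@dataclass
class HydropathyProfile:
    """Moving-average hydropathy: positions are 1-based window centres."""

    positions: np.ndarray
    score: np.ndarray
    window: int
    scale_name: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.score = np.asarray(self.score, dtype=np.float64)
        if len(self.positions) != len(self.score):
            raise ValueError("positions and scores must align")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position (residue)": self.positions, "hydropathy (scale units)": self.score}
        )

    def to_dict(self) -> dict:
        return {
            "kind": "hydropathy_profile",
            "positions": self.positions.tolist(),
            "score": self.score.tolist(),
            "window": self.window,
            "scale": self.scale_name,
        }


def hydropathy_profile(
    seq: str, scale: HydropathyScale = ROSEMAN, window: int = 9
) -> HydropathyProfile:
    """Centred moving-average hydropathy of `seq` with an odd `window`.

    Window 1 (an explicit override) degenerates to the per-residue lookup.
    Raises on even windows, sequences shorter than the window, and any
    non-standard residue letter (named with its 1-based position).
    """
    seq = seq.upper()
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    if len(seq) < window:
        raise ValueError(f"sequence length {len(seq)} shorter than window {window}")
    for i, ch in enumerate(seq, start=1):
        if ch not in _STANDARD_AA:
            raise ValueError(f"non-standard residue {ch!r} at position {i}")
    per_residue = np.array([scale[ch] for ch in seq])
    kernel = np.full(window, 1.0 / window)
    score = np.convolve(per_residue, kernel, mode="valid")
    half = window // 2
    positions = np.arange(1 + half, len(seq) - half + 1)
    return HydropathyProfile(positions, score, window, scale.name)


def profile_delta(
    profile_mut: HydropathyProfile,
    profile_wt: HydropathyProfile,
    summary_range: tuple[int, int] | None = None,
) -> tuple[np.ndarray, float]:
    """Element-wise mutant − wild-type profile difference.

    Returns ``(delta, summary)`` where `summary` is the mean delta over the
    inclusive residue-position `summary_range` (whole profile when None).
    Profiles must share length and window.
    """
    if profile_mut.window != profile_wt.window:
        raise ValueError("profiles computed with different windows")
    if len(profile_mut.score) != len(profile_wt.score):
        raise ValueError("profiles differ in length")
    delta = profile_mut.score - profile_wt.score
    if summary_range is None:
        return delta, float(delta.mean())
    lo, hi = summary_range
    mask = (profile_wt.positions >= lo) & (profile_wt.positions <= hi)
    if not np.any(mask):
        raise ValueError(f"no profile positions inside range {summary_range}")
    return delta, float(delta[mask].mean())


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read sequences from FASTA, keyed by record id (order preserved)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
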