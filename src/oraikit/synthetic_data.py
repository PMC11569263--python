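"""Ground-truth generators for every stage of the analysis pipeline.

Real inputs for this package are MD trajectory frames of a hexameric channel
and confocal microscopy rasters; neither is needed to validate the analysis
machinery.  The generators here build:

* a pseudo-hexameric channel — vertical Cα rods per TM helix arranged in
  rings, a pseudo-Cγ side chain planted at a von Mises-distributed
  membrane-plane orientation, and waters placed as homogeneous Poisson point
  processes inside chosen regions (pore cylinder, per-subunit shell around
  the chosen residue);
* 3-cube FRET image triples composed by inverting the sensitized-emission
  efficiency equation for a planted per-cell E, with planted bleed-through
  factors and optional Poisson shot noise;
* NFAT cell populations with planted nucleus/cytosol intensity ratios.

Every generator is deterministic under a fixed seed and returns its ground
truth next to the data, so recovery tests never re-derive truth from the
generated artifact.  Poisson water placement is deliberately the weakest
statistical assumption that still validates counting and binning machinery;
it does not emulate correlated water dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .imaging_quant import FretCalibration, ImageTriple
from .trajectory_model import Frame, Trajectory

__all__ = [
    "ChannelSpec",
    "ImageSpec",
    "build_channel",
    "make_ring_frame",
    "make_fret_images",
    "make_nfat_population",
]

_SUBUNIT_IDS = "ABCDEFGHIJ"

#: Default TM helix ring radii (Å) and residue ranges (human Orai1 numbering):
#: TM1 lines the pore, TM2/TM3 form the middle ring, TM4 the periphery.
DEFAULT_HELIX_RADII = {"TM1": 8.0, "TM2": 14.0, "TM3": 18.0, "TM4": 22.0}
DEFAULT_RESIDUE_RANGES = {
    "TM1": (80, 110),
    "TM2": (120, 150),
    "TM3": (170, 195),
    "TM4": (235, 262),
}


@dataclass
class ChannelSpec:
    """Parameters of the synthetic pseudo-hexameric channel."""

    n_subunits: int = 6
    helix_radii: dict = field(default_factory=lambda: dict(DEFAULT_HELIX_RADII))
    residue_ranges: dict = field(default_factory=lambda: dict(DEFAULT_RESIDUE_RANGES))
    ca_spacing: float = 1.5  # axial rise per residue, Å
    sidechain_residue: int = 181
    sidechain_bond_length: float = 1.5  # Cα-Cγ pseudo-bond, Å, in-plane
    orientation_mu_deg: float = 60.0  # planted side-chain angle vs pore direction
    orientation_kappa: float = 8.0  # von Mises concentration; 0 = fixed at mu
    pore_water_density: float = 0.0  # Å^-3 inside the pore cylinder
    pore_water_radius: float = 10.0
    pore_water_half_height: float = 10.0
    shell_water_density: float = 0.0  # Å^-3 inside each per-subunit shell
    shell_water_count: int | None = None  # exact count per shell, overrides density
    shell_cutoff: float = 6.0
    n_frames: int = 1
    n_replicas: int = 1
    dt_ns: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_subunits <= len(_SUBUNIT_IDS):
            raise ValueError("n_subunits must be in 1..10")
        if any(r <= 1.7 for r in self.helix_radii.values()):
            raise ValueError("helix ring radii must exceed a carbon vdW radius")
        if min(self.pore_water_density, self.shell_water_density) < 0:
            raise ValueError("water densities must be >= 0")
        if self.orientation_kappa < 0:
            raise ValueError("orientation kappa must be >= 0")
        tm3 = self.residue_ranges["TM3"]
        if not tm3[0] <= self.sidechain_residue <= tm3[1]:
            raise ValueError("sidechain residue must lie inside the TM3 range")


def _uniform_in_sphere(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return v * r[:, None]


def _uniform_in_cylinder(
    rng: np.random.Generator, n: int, radius: float, half_height: float
) -> np.ndarray:
    r = radius * np.sqrt(rng.random(n))
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    z = rng.uniform(-half_height, half_height, n)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def build_channel(spec: ChannelSpec) -> tuple[list[Trajectory], dict]:
    """Generate replica trajectories of the synthetic channel.

    Returns ``(replicas, truth)`` where `truth` records, per replica/frame,
    the planted side-chain deviation angles (degrees, signed), the number of
    pore-cylinder waters and the per-subunit shell water counts.
    """
    angles_truth = np.zeros((spec.n_replicas, spec.n_frames, spec.n_subunits))
    pore_counts = np.zeros((spec.n_replicas, spec.n_frames), dtype=int)
    shell_counts = np.zeros(
        (spec.n_replicas, spec.n_frames, spec.n_subunits), dtype=int
    )
    replicas = []
    for rep in range(spec.n_replicas):
        rng = np.random.default_rng([int(spec.seed), rep])
        raw = []
        for fi in range(spec.n_frames):
            frame, deg, n_pore, n_shell = _build_frame(spec, rng)
            frame.time = fi * spec.dt_ns
            raw.append(frame)
            angles_truth[rep, fi] = deg
            pore_counts[rep, fi] = n_pore
            shell_counts[rep, fi] = n_shell
        replicas.append(Trajectory(frames=_pad_waters(raw), replica_id=rep))
    truth = {
        "orientation_deg": angles_truth,
        "pore_water_counts": pore_counts,
        "shell_water_counts": shell_counts,
        "mu_deg": spec.orientation_mu_deg,
        "kappa": spec.orientation_kappa,
    }
    return replicas, truth


#: Reservoir waters sit this far out on x, well clear of any analysis region.
_RESERVOIR_X = 500.0


def _pad_waters(frames: list[Frame]) -> list[Frame]:
    """Pad every frame to a common water count with distant reservoir waters.

    Per-frame Poisson placement yields varying water counts, but a trajectory
    (like any MD trajectory file) must keep one atom count and ordering.  The
    pad waters are parked hundreds of Å from the channel so no cylinder,
    shell or histogram within the structure can ever see them.
    """
    n_max = max(f.n_atoms for f in frames)
    out = []
    for f in frames:
        k = n_max - f.n_atoms
        if k == 0:
            out.append(f)
            continue
        pad_pos = np.column_stack(
            [
                _RESERVOIR_X + 3.0 * np.arange(k),
                np.zeros(k),
                np.zeros(k),
            ]
        )
        # waters are numbered 1..n per frame; continue so every padded frame
        # carries identical annotations (required for multi-MODEL output)
        start = int(np.sum(f.residue_names == "SOL")) + 1
        out.append(
            Frame(
                atom_names=list(f.atom_names) + ["OW"] * k,
                elements=list(f.elements) + ["O"] * k,
                residue_names=list(f.residue_names) + ["SOL"] * k,
                residue_numbers=list(f.residue_numbers) + list(range(start, start + k)),
                subunit_ids=list(f.subunit_ids) + ["W"] * k,
                positions=np.vstack([f.positions, pad_pos]),
                time=f.time,
            )
        )
    return out


def _build_frame(spec: ChannelSpec, rng: np.random.Generator):
    names, elements, resnames, resnums, chains, coords = [], [], [], [], [], []

    def add(name, el, resname, resnum, chain, xyz):
        names.append(name)
        elements.append(el)
        resnames.append(resname)
        resnums.append(resnum)
        chains.append(chain)
        coords.append(xyz)

    theta = 2.0 * np.pi * np.arange(spec.n_subunits) / spec.n_subunits
    deg_truth = np.zeros(spec.n_subunits)
    sidechain_ca = np.zeros((spec.n_subunits, 3))
    for s in range(spec.n_subunits):
        chain = _SUBUNIT_IDS[s]
        ct, st = np.cos(theta[s]), np.sin(theta[s])
        for helix, (lo, hi) in spec.residue_ranges.items():
            radius = spec.helix_radii[helix]
            mid = 0.5 * (lo + hi)
            for resnum in range(lo, hi + 1):
                z = (resnum - mid) * spec.ca_spacing
                pos = np.array([radius * ct, radius * st, z])
                add("CA", "C", "ALA", resnum, chain, pos)
                if resnum == spec.sidechain_residue and helix == "TM3":
                    sidechain_ca[s] = pos
        # pseudo-Cγ at the planted membrane-plane orientation: deviation from
        # the pore-pointing direction drawn from von Mises(mu, kappa)
        mu = np.radians(spec.orientation_mu_deg)
        delta = rng.vonmises(mu, spec.orientation_kappa) if spec.orientation_kappa > 0 else mu
        deg_truth[s] = np.degrees(delta)
        phi = theta[s] + np.pi + delta  # theta + pi points at the pore axis
        cg = sidechain_ca[s] + spec.sidechain_bond_length * np.array(
            [np.cos(phi), np.sin(phi), 0.0]
        )
        add("CG", "C", "ALA", spec.sidechain_residue, chain, cg)

    wat_resnum = 1
    n_pore = 0
    if spec.pore_water_density > 0:
        vol = np.pi * spec.pore_water_radius**2 * 2 * spec.pore_water_half_height
        n_pore = int(rng.poisson(spec.pore_water_density * vol))
        for w in _uniform_in_cylinder(
            rng, n_pore, spec.pore_water_radius, spec.pore_water_half_height
        ):
            add("OW", "O", "SOL", wat_resnum, "W", w)
            wat_resnum += 1
    n_shell = np.zeros(spec.n_subunits, dtype=int)
    if spec.shell_water_count is not None or spec.shell_water_density > 0:
        for s in range(spec.n_subunits):
            if spec.shell_water_count is not None:
                k = spec.shell_water_count
            else:
                vol = 4.0 / 3.0 * np.pi * spec.shell_cutoff**3
                k = int(rng.poisson(spec.shell_water_density * vol))
            n_shell[s] = k
            for w in _uniform_in_sphere(rng, k, spec.shell_cutoff):
                add("OW", "O", "SOL", wat_resnum, "W", sidechain_ca[s] + w)
                wat_resnum += 1

    frame = Frame(
        atom_names=names,
        elements=elements,
        residue_names=resnames,
        residue_numbers=resnums,
        subunit_ids=chains,
        positions=np.asarray(coords),
    )
    return frame, deg_truth, n_pore, n_shell


def make_ring_frame(
    ring_radius: float = 8.0,
    n_atoms: int = 12,
    vdw: float = 1.70,
    center_xy: tuple[float, float] = (0.0, 0.0),
    z: float = 0.0,
    residue_start: int = 80,
) -> Frame:
    """A single ring of carbon pseudo-atoms in the z-plane — the analytic
    test case for the pore-radius search (slice radius = ring − vdW)."""
    phi = 2.0 * np.pi * np.arange(n_atoms) / n_atoms
    pos = np.column_stack(
        [
            center_xy[0] + ring_radius * np.cos(phi),
            center_xy[1] + ring_radius * np.sin(phi),
            np.full(n_atoms, z),
        ]
    )
    return Frame(
        atom_names=["CA"] * n_atoms,
        elements=["C"] * n_atoms,
        residue_names=["ALA"] * n_atoms,
        residue_numbers=np.arange(residue_start, residue_start + n_atoms),
        subunit_ids=["A"] * n_atoms,
        positions=pos,
        vdw_radii=np.full(n_atoms, vdw),
    )


@dataclass
class ImageSpec:
    """Parameters of synthetic microscopy fields (FRET triples / NFAT)."""

    shape: tuple[int, int] = (256, 256)
    background: float = 50.0  # counts, per channel
    n_cells: int = 4
    cell_radius: int = 9
    nucleus_radius: int = 4
    # FRET composition
    e_true: float | Sequence[float] = 0.3
    a: float = 0.1
    b: float = 0.5
    G: float = 2.75
    cfp_level: float = 1000.0  # donor-channel counts inside a cell
    yfp_level: float = 1000.0
    # NFAT composition
    ratios: Sequence[float] | None = None  # per-cell nucleus/cytosol ratio
    category_fractions: tuple[float, float, float] | None = None
    cytosol_level: float = 1000.0
    noise: str = "none"  # "none" | "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise not in ("none", "poisson"):
            raise ValueError("noise must be 'none' or 'poisson'")
        if self.background < 0:
            raise ValueError("background must be >= 0")


def _cell_centers(spec: ImageSpec) -> list[tuple[int, int]]:
    pitch = 2 * spec.cell_radius + 6
    h, w = spec.shape
    per_row = max((w - spec.cell_radius) // pitch, 1)
    centers = []
    for i in range(spec.n_cells):
        r = spec.cell_radius + 3 + (i // per_row) * pitch
        c = spec.cell_radius + 3 + (i % per_row) * pitch
        if r + spec.cell_radius >= h or c + spec.cell_radius >= w:
            raise ValueError(
                f"{spec.n_cells} cells of radius {spec.cell_radius} do not fit "
                f"into a {spec.shape} image without overlap"
            )
        centers.append((r, c))
    return centers


def _disc_mask(shape, center, radius) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def make_fret_images(spec: ImageSpec) -> tuple[ImageTriple, dict]:
    """Compose a CFP/YFP/FRET triple with planted per-cell FRET efficiency.

    The FRET channel is built by inverting the efficiency equation: with
    measured donor signal C the sensitized emission is
    ``F_c = G·C·E/(1−E)``, and ``I_FRET = a·I_YFP + b·I_CFP + F_c``.
    Backgrounds are added afterwards and, with ``noise='poisson'``, every
    pixel is drawn from a Poisson law at its expected count.
    """
    e_list = (
        [float(spec.e_true)] * spec.n_cells
        if np.isscalar(spec.e_true)
        else [float(e) for e in spec.e_true]
    )
    if len(e_list) != spec.n_cells:
        raise ValueError("need one planted E per cell")
    if any(not 0.0 <= e < 1.0 for e in e_list):
        raise ValueError("planted E must lie in [0, 1)")
    cal = FretCalibration(spec.a, spec.b, spec.G)
    h, w = spec.shape
    cfp = np.zeros((h, w))
    yfp = np.zeros((h, w))
    fret = np.zeros((h, w))
    labels = np.zeros((h, w), dtype=np.int32)
    for k, (center, e) in enumerate(zip(_cell_centers(spec), e_list), start=1):
        mask = _disc_mask(spec.shape, center, spec.cell_radius)
        labels[mask] = k
        c_level = spec.cfp_level
        y_level = spec.yfp_level
        f_c = spec.G * c_level * e / (1.0 - e)
        cfp[mask] = c_level
        yfp[mask] = y_level
        fret[mask] = spec.a * y_level + spec.b * c_level + f_c
    cfp += spec.background
    yfp += spec.background
    fret += spec.background
    if spec.noise == "poisson":
        rng = np.random.default_rng(int(spec.seed))
        cfp = rng.poisson(cfp).astype(float)
        yfp = rng.poisson(yfp).astype(float)
        fret = rng.poisson(fret).astype(float)
    triple = ImageTriple(
        I_CFP=cfp,
        I_YFP=yfp,
        I_FRET=fret,
        background=(spec.background,) * 3,
    )
    truth = {"labels": labels, "e_true": e_list, "calibration": cal}
    return triple, truth


def _resolve_ratios(spec: ImageSpec) -> tuple[list[float], list[str]]:
    from .imaging_quant import nfat_classify

    if spec.ratios is not None:
        ratios = [float(r) for r in spec.ratios]
        if len(ratios) != spec.n_cells:
            raise ValueError("need one planted ratio per cell")
    elif spec.category_fractions is not None:
        fr = np.asarray(spec.category_fractions, dtype=float)
        if abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError("category fractions must sum to 1")
        # largest-remainder apportionment keeps planted fractions exact
        raw = fr * spec.n_cells
        counts = np.floor(raw).astype(int)
        remainder = spec.n_cells - counts.sum()
        for i in np.argsort(raw - counts)[::-1][:remainder]:
            counts[i] += 1
        representative = (0.5, 1.0, 1.5)  # inactive / homogeneous / active
        ratios = [
            representative[j] for j, n in enumerate(counts) for _ in range(n)
        ]
    else:
        raise ValueError("ImageSpec needs `ratios` or `category_fractions` for NFAT")
    if any(r <= 0 for r in ratios):
        raise ValueError("planted ratios must be > 0")
    categories = [nfat_classify(r, 1.0) for r in ratios]
    return ratios, categories


def make_nfat_population(spec: ImageSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Synthesize an NFAT field: intensity image plus per-cell label masks.

    Each cell is a disc of cytosol at `cytosol_level` with an inner nuclear
    disc at ``ratio × cytosol_level``; the cytosol mask is the annulus.
    Returns ``(image, nucleus_labels, cytosol_labels, truth)``.
    """
    ratios, categories = _resolve_ratios(spec)
    h, w = spec.shape
    image = np.full((h, w), float(spec.background))
    nuc_labels = np.zeros((h, w), dtype=np.int32)
    cyt_labels = np.zeros((h, w), dtype=np.int32)
    for k, (center, ratio) in enumerate(zip(_cell_centers(spec), ratios), start=1):
        cell = _disc_mask(spec.shape, center, spec.cell_radius)
        nuc = _disc_mask(spec.shape, center, spec.nucleus_radius)
        cyt = cell & ~nuc
        image[cyt] = spec.background + spec.cytosol_level
        image[nuc] = spec.background + ratio * spec.cytosol_level
        nuc_labels[nuc] = k
        cyt_labels[cyt] = k
    if spec.noise == "poisson":
        rng = np.random.default_rng(int(spec.seed))
        image = rng.poisson(image).astype(float)
    truth = {"ratios": ratios, "categories": categories}
    return image, nuc_labels, cyt_labels, truth
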