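import numpy as np
import pytest

from oraikit import ChannelSpec, build_channel
from oraikit.trajectory_model import Frame


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def dry_channel():
    """One-frame, water-free hexamer and its ground truth (fixed orientation)."""
    spec = ChannelSpec(orientation_kappa=0.0, n_frames=1, n_replicas=1, seed=7)
    trajs, truth = build_channel(spec)
    return trajs[0].frames[0], truth


def water_frame(positions, time=0.0):
    """Frame containing only water oxygens at the given positions."""
    n = len(positions)
    return Frame(
        atom_names=["OW"] * n,
        elements=["O"] * n,
        residue_names=["SOL"] * n,
        residue_numbers=np.arange(1, n + 1),
        subunit_ids=["W"] * n,
        positions=np.asarray(positions, dtype=float).reshape(n, 3),
        time=time,
    )


def point_frame(points, atom_name="CA", residue_numbers=None, subunit="A", vdw=1.70):
    """Frame of bare pseudo-atoms at the given points (test geometry helper)."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    n = len(pts)
    return Frame(
        atom_names=[atom_name] * n,
        elements=["C"] * n,
        residue_names=["ALA"] * n,
        residue_numbers=(
            np.arange(80, 80 + n) if residue_numbers is None else residue_numbers
        ),
        subunit_ids=[subunit] * n,
        positions=pts,
        vdw_radii=np.full(n, vdw),
    )
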