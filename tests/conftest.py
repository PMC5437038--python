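import numpy as np
import pytest

from loxshield import SceneSpec, ShieldingConfig, Snapshot, build_scene
from loxshield.structure_io import AtomRecord


@pytest.fixture
def config():
    return ShieldingConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def make_snapshot(atom_rows, pentadiene_ids=None, iron_id=None, label="test"):
    """Build a Snapshot from rows of
    (serial, name, element, resname, resid, chain, (x, y, z))."""
    atoms = [
        AtomRecord(serial, name, element, resname, resid, chain, np.array(pos))
        for serial, name, element, resname, resid, chain, pos in atom_rows
    ]
    return Snapshot(
        atoms=atoms, pentadiene_ids=pentadiene_ids, iron_id=iron_id, label=label
    )


def pocket_snapshot(blockers=(), iron_z=-3.0):
    """Planar pentadiene in z=0 along x, iron below the plane, optional
    blocker atoms given as (name, position) on the +z (antarafacial) side."""
    rows = []
    for i in range(5):
        rows.append((i + 1, f"C{9 + i}", "C", "LNR", 1, "S", (1.4 * i, 0.3 * (i % 2), 0.0)))
    rows.append((6, "FE", "Fe", "FE2", 1, "M", (2.8, 0.0, iron_z)))
    serial = 7
    for name, pos in blockers:
        rows.append((serial, name, "C", "BLK", serial, "B", tuple(pos)))
        serial += 1
    return make_snapshot(rows, pentadiene_ids=(1, 2, 3, 4, 5), iron_id=6)


@pytest.fixture
def small_scene():
    spec = SceneSpec(
        blocker_distance={"C9": "OPEN", "C11": 1.0, "C13": 2.0},
        n_snapshots=20,
        jitter_sigma=0.05,
        dihedral_sigma=3.0,
        seed=11,
    )
    ensemble, truth = build_scene(spec)
    return spec, ensemble, truth
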