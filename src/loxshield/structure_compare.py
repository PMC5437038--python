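"""Rigid-body structural comparison utilities.

Optimal least-squares superposition (Kabsch), rotation-angle extraction
(e.g. the near-180-degree rotation relating the two chains of a
pseudo-symmetric homodimer), Cα pairing between chains, a
sequence-independent iterative-closest-Cα alignment for structures of
different sequence, and the active-site-clamp residue correspondence table
across lipoxygenases (reference row: CspLOX2 Leu258, Ile296, Ala300,
Leu304, Leu502, Leu506).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .structure_io import Snapshot

__all__ = [
    "Superposition",
    "ClampResidueTable",
    "kabsch_superpose",
    "rotation_angle",
    "chain_pairing",
    "align_structures",
    "load_clamp_table",
    "clamp_table_lookup",
]

#: CspLOX2 clamp residues, positions 1..6.
CLAMP_REFERENCE = ("Leu258", "Ile296", "Ala300", "Leu304", "Leu502", "Leu506")


@dataclass
class Superposition:
    """Optimal rigid motion mapping coordinate set B onto set A:
    ``x -> rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def kabsch_superpose(coords_a, coords_b) -> Superposition:
    """Least-squares optimal superposition of B onto A (paired points).

    A proper rotation (det +1) is enforced, so mirror images are not
    matched.  RMSD is evaluated after applying the recovered motion.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"paired (n, 3) coordinate sets required, got {a.shape} vs {b.shape}")
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 paired atoms")
    centroid_a = a.mean(axis=0)
    centroid_b = b.mean(axis=0)
    a_c = a - centroid_a
    b_c = b - centroid_b
    if np.linalg.matrix_rank(a_c, tol=1e-8) < 2 or np.linalg.matrix_rank(b_c, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) coordinates; rotation not unique")
    rot, _ = Rotation.align_vectors(a_c, b_c)
    matrix = rot.as_matrix()
    translation = centroid_a - matrix @ centroid_b
    moved = b @ matrix.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - a) ** 2, axis=1))))
    return Superposition(rotation=matrix, translation=translation, rmsd=rmsd, n_atoms=n)


def rotation_angle(rotation: np.ndarray) -> float:
    """Rotation angle in degrees, [0, 180], from the matrix trace."""
    r = np.asarray(rotation, dtype=float)
    if r.shape != (3, 3):
        raise ValueError("rotation must be a 3x3 matrix")
    if not np.allclose(r @ r.T, np.eye(3), atol=1e-6) or not np.isclose(
        np.linalg.det(r), 1.0, atol=1e-6
    ):
        raise ValueError("matrix is not a proper rotation")
    cos_angle = np.clip((np.trace(r) - 1.0) / 2.0, -1.0, 1.0)
    return float(np.degrees(np.arccos(cos_angle)))


def _calpha_by_residue(snapshot: Snapshot, chain_id: str) -> dict[int, np.ndarray]:
    out = {}
    for atom in snapshot.atoms:
        if (
            atom.chain_id == chain_id
            and atom.name == "CA"
            and atom.element.capitalize() == "C"
        ):
            out[atom.residue_number] = atom.position
    return out


def chain_pairing(
    snapshot: Snapshot, chain_a: str, chain_b: str
) -> tuple[np.ndarray, np.ndarray]:
    """Pair Cα atoms of two same-sequence chains by residue number.

    Residues modeled in only one chain are dropped.  Returns the two
    (n, 3) coordinate arrays in matching residue order.
    """
    ca_a = _calpha_by_residue(snapshot, chain_a)
    ca_b = _calpha_by_residue(snapshot, chain_b)
    shared = sorted(set(ca_a) & set(ca_b))
    if not shared:
        raise ValueError(f"chains {chain_a!r} and {chain_b!r} share no Cα residues")
    return (
        np.array([ca_a[r] for r in shared]),
        np.array([ca_b[r] for r in shared]),
    )


def _principal_axis_seeds(a_c: np.ndarray, b_c: np.ndarray) -> list[np.ndarray]:
    """Candidate rotations aligning B's principal axes onto A's (the four
    proper sign combinations), used to seed the iterative alignment."""
    _, _, vt_a = np.linalg.svd(a_c, full_matrices=False)
    _, _, vt_b = np.linalg.svd(b_c, full_matrices=False)
    seeds = []
    for sx, sy in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        signs = np.diag([sx, sy, sx * sy])
        candidate = vt_a.T @ signs @ vt_b
        if np.linalg.det(candidate) < 0:
            candidate = vt_a.T @ signs @ np.diag([1, 1, -1]) @ vt_b
        seeds.append(candidate)
    return seeds


def align_structures(
    coords_a,
    coords_b,
    pair_cutoff: float = 5.0,
    max_iter: int = 60,
) -> tuple[Superposition, list[tuple[int, int]]]:
    """Sequence-independent Cα alignment of two structures.

    Seeds from principal-axis alignment (all proper sign choices), then
    iterates mutual-nearest-neighbor pairing within ``pair_cutoff`` Å and
    Kabsch refitting until the pairing stabilizes; the seed giving the most
    pairs (ties: lowest RMSD) wins.  Returns the final superposition (B
    onto A) and the paired index list.  Intended for homologous folds of
    different sequence, where residue-number pairing is meaningless.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    centroid_a = a.mean(axis=0)
    centroid_b = b.mean(axis=0)
    best: tuple[Superposition, list[tuple[int, int]]] | None = None
    for seed in _principal_axis_seeds(a - centroid_a, b - centroid_b):
        translation = centroid_a - seed @ centroid_b
        moved = b @ seed.T + translation
        pairs_prev: list[tuple[int, int]] = []
        sup = None
        for _ in range(max_iter):
            pairs = _mutual_nearest_pairs(a, moved, pair_cutoff)
            if len(pairs) < 3:
                break
            if pairs == pairs_prev:
                break
            pairs_prev = pairs
            ia = [i for i, _ in pairs]
            ib = [j for _, j in pairs]
            sup = kabsch_superpose(a[ia], b[ib])
            moved = sup.transform(b)
        if sup is None or len(pairs_prev) < 3:
            continue
        if (
            best is None
            or len(pairs_prev) > len(best[1])
            or (len(pairs_prev) == len(best[1]) and sup.rmsd < best[0].rmsd)
        ):
            best = (sup, pairs_prev)
    if best is None:
        raise ValueError("alignment failed: no seed produced >= 3 stable pairs")
    return best


def _mutual_nearest_pairs(
    a: np.ndarray, b_moved: np.ndarray, cutoff: float
) -> list[tuple[int, int]]:
    tree_a = cKDTree(a)
    tree_b = cKDTree(b_moved)
    d_ab, nn_ab = tree_b.query(a, k=1, distance_upper_bound=cutoff)
    _, nn_ba = tree_a.query(b_moved, k=1, distance_upper_bound=cutoff)
    pairs = []
    for i, (dist, j) in enumerate(zip(d_ab, nn_ab)):
        if np.isfinite(dist) and j < len(b_moved) and nn_ba[j] == i:
            pairs.append((i, int(j)))
    return pairs


# ---------------------------------------------------------------------------
# Active-site-clamp residue table
# ---------------------------------------------------------------------------

@dataclass
class ClampResidueTable:
    """Per-enzyme clamp residues at the six positions homologous to the
    CspLOX2 reference, plus each enzyme's main product."""

    rows: dict[str, tuple[str, ...]]
    main_products: dict[str, str]

    def __post_init__(self) -> None:
        for enzyme, labels in self.rows.items():
            if len(labels) != 6:
                raise ValueError(f"{enzyme}: expected 6 clamp residues, got {len(labels)}")
        reference = self.rows.get("CspLOX2")
        if reference is not None and tuple(reference) != CLAMP_REFERENCE:
            raise ValueError(f"CspLOX2 row {reference} does not match {CLAMP_REFERENCE}")


def load_clamp_table(path: str | Path | None = None) -> ClampResidueTable:
    """Load the packaged clamp-residue correspondence table (or a CSV with
    the same columns)."""
    if path is None:
        source = resources.files("loxshield.data") / "clamp_residues.csv"
        with resources.as_file(source) as p:
            table = pd.read_csv(p)
    else:
        table = pd.read_csv(path)
    rows = {}
    products = {}
    for _, record in table.iterrows():
        rows[record["enzyme"]] = tuple(
            record[f"pos{i}"] for i in range(1, 7)
        )
        products[record["enzyme"]] = record["main_product"]
    return ClampResidueTable(rows=rows, main_products=products)


def clamp_table_lookup(
    enzyme: str, position: int, table: ClampResidueTable | None = None
) -> str:
    """Residue label of ``enzyme`` at clamp position 1..6."""
    table = table or load_clamp_table()
    if enzyme not in table.rows:
        raise KeyError(f"unknown enzyme {enzyme!r}; known: {sorted(table.rows)}")
    if not 1 <= position <= 6:
        raise ValueError(f"position must be 1..6, got {position}")
    return table.rows[enzyme][position - 1]
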