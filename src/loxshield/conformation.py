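"""Substrate dihedral-angle analysis across snapshot ensembles.

The two internal torsions of the pentadiene, C9-C10-C11-C12 and
C10-C11-C12-C13, report on how planar the bound substrate radical is; a
planar (s-trans, 180 deg) pentadiene keeps the radical delocalized over
C9/C11/C13.  Ensemble histograms of these torsions show whether an enzyme
twists the substrate out of plane or, as for the wild type and all clamp
mutants, leaves a distribution peaked near planarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .structure_io import TrajectoryEnsemble

__all__ = [
    "DEFAULT_QUADRUPLES",
    "DihedralSeries",
    "dihedral_angle",
    "dihedral_series",
    "dihedral_histogram",
    "series_to_csv",
    "histogram_to_csv",
]

#: The two pentadiene torsions, as index quadruples into the C9..C13 chain.
DEFAULT_QUADRUPLES = ((0, 1, 2, 3), (1, 2, 3, 4))

_DEGENERACY_TOL = 1e-8


@dataclass
class DihedralSeries:
    """One torsion tracked over an ensemble: atom ids, one signed angle in
    (-180, 180] degrees per snapshot."""

    quadruple: tuple[int, int, int, int]
    angles: np.ndarray
    ensemble_label: str = ""

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if np.any(self.angles <= -180.0) or np.any(self.angles > 180.0):
            raise ValueError("angles must lie in (-180, 180]")


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, IUPAC convention,
    range (-180, 180] with 180 = planar trans."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for a, b, name in ((p1, p2, "p1-p2"), (p2, p3, "p2-p3"), (p3, p4, "p3-p4")):
        if np.linalg.norm(b - a) < _DEGENERACY_TOL:
            raise ValueError(f"coincident points {name}")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _DEGENERACY_TOL or np.linalg.norm(n2) < _DEGENERACY_TOL:
        raise ValueError("collinear triple; torsion undefined")
    b2_unit = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2_unit))
    angle = np.degrees(np.arctan2(y, x))
    if angle <= -180.0:
        angle += 360.0
    return float(angle)


def dihedral_series(
    ensemble: TrajectoryEnsemble, quadruple: tuple[int, int, int, int]
) -> DihedralSeries:
    """One torsion value per snapshot (atom serials), order preserved."""
    angles = []
    for snap in ensemble:
        points = [snap.position(serial) for serial in quadruple]
        angles.append(dihedral_angle(*points))
    return DihedralSeries(
        quadruple=tuple(quadruple),
        angles=np.array(angles),
        ensemble_label=ensemble.replicate_label,
    )


def dihedral_histogram(
    series: DihedralSeries, bin_width: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """Circular histogram with 180 deg at a bin center.

    Returns ``(centers, counts)``: centers ascending in (-180, 180],
    ``360 / bin_width`` bins, counts summing to the number of snapshots.
    Values are binned on the circle, so -179 deg and the 181-deg-equivalent
    land in the same bin.
    """
    n_bins = 360.0 / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9 or bin_width <= 0:
        raise ValueError(f"bin width {bin_width} must divide 360 evenly")
    n_bins = int(round(n_bins))
    # shift so that the bin containing 180 is centered on it
    shifted = np.mod(series.angles - (180.0 - bin_width / 2.0), 360.0)
    indices = np.minimum((shifted // bin_width).astype(int), n_bins - 1)
    counts = np.bincount(indices, minlength=n_bins)
    centers = 180.0 + bin_width * np.arange(n_bins)
    centers = np.mod(centers - 180.0, 360.0) - 180.0
    centers[centers == -180.0] = 180.0
    order = np.argsort(centers)
    return centers[order], counts[order]


def series_to_csv(series: DihedralSeries, path: str | Path) -> None:
    pd.DataFrame(
        {
            "snapshot": np.arange(len(series.angles)),
            "angle_deg": series.angles,
        }
    ).to_csv(path, index=False)


def histogram_to_csv(
    centers: np.ndarray, counts: np.ndarray, path: str | Path
) -> None:
    pd.DataFrame({"bin_center_deg": centers, "count": counts}).to_csv(
        path, index=False
    )
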