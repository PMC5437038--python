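"""Per-snapshot geometry of the steric-shielding model.

For each frame of an active-site ensemble the model places a mean plane
through the five carbons of the substrate pentadiene (C9..C13 of the
linoleic-acid radical), orients its normal to the antarafacial side (the
face opposite the catalytic iron, the only face on which O2 can add in this
system), and puts a probe point 3 Å from each reactive carbon (C9, C11,
C13) along that normal — the position molecular oxygen would occupy in the
pre-reactive complex.  The distance from the probe to the nearest
non-substrate atom is then mapped to an accessibility score in [0, 1]:

* no atom within ``r_open`` (default 2.2 Å)  -> fully accessible, score 1;
* an atom within ``r_block`` (default 1.8 Å) -> fully shielded, score 0;
* in between, a smooth exponential ramp
  ``g(d) = (exp(k*u) - 1) / (exp(k) - 1)`` with
  ``u = (d - r_block) / (r_open - r_block)`` and steepness ``k`` (default 2),
  which absorbs thermal fluctuations without hard on/off switching.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.spatial import cKDTree

from .structure_io import Snapshot, TrajectoryEnsemble

__all__ = [
    "OPEN",
    "ShieldingConfig",
    "PlaneFit",
    "ProbeSite",
    "REACTIVE_CARBONS",
    "fit_pentadiene_plane",
    "orient_antarafacial",
    "build_probe_points",
    "min_blocker_distance",
    "accessibility_score",
    "snapshot_accessibility",
    "ensemble_accessibility",
]

#: Sentinel distance for "no blocker within r_open": the site is fully open.
OPEN = math.inf

#: Reactive carbons, as (label, index into the 5-atom pentadiene chain).
REACTIVE_CARBONS = (("C9", 0), ("C11", 2), ("C13", 4))

BLOCKER_POLICIES = ("protein-only", "protein+water", "all-non-substrate")

#: Iron closer than this (Å) to the pentadiene plane leaves the
#: antarafacial side undefined.
SIDE_DEGENERACY_THRESHOLD = 0.1


@dataclass
class ShieldingConfig:
    """Tunable parameters of the shielding model (distances in Å)."""

    d_probe: float = 3.0
    r_open: float = 2.2
    r_block: float = 1.8
    ramp_steepness: float = 2.0
    blocker_policy: str = "all-non-substrate"
    include_hydrogens: bool = True
    c11_penalty: float = 0.10

    def __post_init__(self) -> None:
        if not self.r_block < self.r_open:
            raise ValueError(
                f"need r_block < r_open (got {self.r_block}, {self.r_open})"
            )
        if self.d_probe < 0:
            raise ValueError("d_probe must be >= 0")
        if self.ramp_steepness <= 0:
            raise ValueError("ramp_steepness must be > 0")
        if not 0 <= self.c11_penalty < 1:
            raise ValueError("c11_penalty must be in [0, 1)")
        if self.blocker_policy not in BLOCKER_POLICIES:
            raise ValueError(
                f"blocker_policy must be one of {BLOCKER_POLICIES}"
            )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ShieldingConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


@dataclass
class PlaneFit:
    """Total-least-squares plane: point cloud centroid, unit normal and the
    RMS point-plane residual (Å).  The normal's sign is arbitrary until
    :func:`orient_antarafacial` resolves it."""

    centroid: np.ndarray
    normal: np.ndarray
    rms_residual: float


@dataclass
class ProbeSite:
    """One reactive carbon's probe point and its nearest-blocker distance
    (``OPEN`` when nothing lies within ``r_open``; ``None`` until
    measured)."""

    carbon_label: str
    carbon_position: np.ndarray
    probe_position: np.ndarray
    min_blocker_distance: float | None = None


def fit_pentadiene_plane(points: Sequence[Sequence[float]]) -> PlaneFit:
    """Fit the mean ("equalization") plane through the five pentadiene
    carbons by total least squares.

    The normal is the smallest-variance principal direction of the centered
    points (right singular vector of the smallest singular value), which
    minimizes the sum of squared point-plane distances.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape != (5, 3):
        raise ValueError(f"expected 5 points in 3D, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite coordinates")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, singular_values, vt = np.linalg.svd(centered, full_matrices=False)
    # collinear points: the two largest variances must both be non-trivial
    if singular_values[1] < 1e-8 * max(singular_values[0], 1.0):
        raise ValueError("pentadiene carbons are (near-)collinear; plane undefined")
    normal = vt[2]
    normal = normal / np.linalg.norm(normal)
    residuals = centered @ normal
    return PlaneFit(
        centroid=centroid,
        normal=normal,
        rms_residual=float(np.sqrt(np.mean(residuals**2))),
    )


def orient_antarafacial(plane: PlaneFit, iron_position: Sequence[float]) -> np.ndarray:
    """Resolve the plane-normal sign so it points away from the iron.

    O2 adds antarafacially, i.e. on the substrate face opposite the
    catalytic metal; the returned unit normal n satisfies
    ``n . (iron - centroid) < 0``.  An iron within
    ``SIDE_DEGENERACY_THRESHOLD`` of the plane leaves no defined side.
    """
    iron = np.asarray(iron_position, dtype=float)
    signed = float(np.dot(plane.normal, iron - plane.centroid))
    if abs(signed) <= SIDE_DEGENERACY_THRESHOLD:
        raise ValueError(
            f"iron is {abs(signed):.3f} Å from the pentadiene plane; "
            "antarafacial side undefined"
        )
    return -plane.normal if signed > 0 else plane.normal


def build_probe_points(
    snapshot: Snapshot, config: ShieldingConfig | None = None
) -> list[ProbeSite]:
    """Probe points for C9, C11 and C13: ``carbon + d_probe * n`` with n the
    antarafacial plane normal."""
    config = config or ShieldingConfig()
    pentadiene = snapshot.pentadiene_positions()
    plane = fit_pentadiene_plane(pentadiene)
    normal = orient_antarafacial(plane, snapshot.iron_position())
    sites = []
    for label, index in REACTIVE_CARBONS:
        carbon = pentadiene[index]
        sites.append(
            ProbeSite(
                carbon_label=label,
                carbon_position=carbon,
                probe_position=carbon + config.d_probe * normal,
            )
        )
    return sites


def _blocker_coordinates(snapshot: Snapshot, config: ShieldingConfig) -> np.ndarray:
    """Atoms that can shield a probe: policy-filtered, always excluding the
    substrate residue(s) and the catalytic iron."""
    substrate = snapshot.substrate_residues()
    iron_id = snapshot.iron_id
    coords = []
    for atom in snapshot.atoms:
        if atom.serial == iron_id:
            continue
        if (atom.chain_id, atom.residue_number) in substrate:
            continue
        if not config.include_hydrogens and atom.element.capitalize() in ("H", "D"):
            continue
        if config.blocker_policy == "protein-only" and not atom.is_protein:
            continue
        if config.blocker_policy == "protein+water" and not (
            atom.is_protein or atom.is_water
        ):
            continue
        coords.append(atom.position)
    if not coords:
        return np.empty((0, 3))
    return np.array(coords)


def min_blocker_distance(
    probe: ProbeSite,
    snapshot: Snapshot,
    config: ShieldingConfig | None = None,
    _tree: cKDTree | None = None,
) -> float:
    """Euclidean distance from the probe point to the nearest blocker;
    :data:`OPEN` when no blocker lies within ``r_open`` (fully accessible).
    """
    config = config or ShieldingConfig()
    if _tree is None:
        coords = _blocker_coordinates(snapshot, config)
        if len(coords) == 0:
            return OPEN
        _tree = cKDTree(coords)
    distance, _ = _tree.query(probe.probe_position, k=1)
    distance = float(distance)
    return OPEN if distance > config.r_open else distance


def accessibility_score(d: float, config: ShieldingConfig | None = None) -> float:
    """Map a nearest-blocker distance to an accessibility fraction.

    1 for ``d >= r_open`` or :data:`OPEN`; 0 for ``d <= r_block``; the
    normalized exponential ramp in between (strictly increasing, continuous
    at both thresholds).
    """
    config = config or ShieldingConfig()
    if d is None:
        raise ValueError("distance is None; use OPEN for open sites")
    if d != OPEN and d < 0:
        raise ValueError(f"negative distance {d}")
    if d >= config.r_open:
        return 1.0
    if d <= config.r_block:
        return 0.0
    u = (d - config.r_block) / (config.r_open - config.r_block)
    k = config.ramp_steepness
    return float(math.expm1(k * u) / math.expm1(k))


def snapshot_accessibility(snapshot: Snapshot, config: ShieldingConfig | None = None):
    """Full per-snapshot evaluation: probes, nearest-blocker distances and
    the (C9, C11, C13) accessibility triple."""
    from .product_model import AccessibilityProfile

    config = config or ShieldingConfig()
    sites = build_probe_points(snapshot, config)
    coords = _blocker_coordinates(snapshot, config)
    tree = cKDTree(coords) if len(coords) else None
    scores = []
    for site in sites:
        if tree is None:
            site.min_blocker_distance = OPEN
        else:
            site.min_blocker_distance = min_blocker_distance(
                site, snapshot, config, _tree=tree
            )
        scores.append(accessibility_score(site.min_blocker_distance, config))
    return AccessibilityProfile(scores=tuple(scores), snapshot_label=snapshot.label)


def ensemble_accessibility(
    ensemble: TrajectoryEnsemble, config: ShieldingConfig | None = None
) -> list:
    """Accessibility profiles for every snapshot, order preserved."""
    config = config or ShieldingConfig()
    return [snapshot_accessibility(snap, config) for snap in ensemble]
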