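"""From per-snapshot accessibilities to predicted product distributions.

Antarafacial O2 attack at C9, C11 or C13 of the pentadienyl radical yields
the 9R-, 11R- and 13S-hydroperoxide respectively, so a distribution over
accessible carbons maps one-to-one onto a distribution over those three
products.  Each snapshot contributes its accessibility triple as fractional
weights (snapshots with all three sites shielded contribute nothing);
trajectory aggregation averages the weights, a bis-allylic penalty moves a
fraction of the C11 product to C9/C13 in equal parts to reflect the higher
activation barrier for oxygen attack at the central carbon, and replicate
runs are averaged unweighted.  Agreement with experimental distributions is
summarized as MAXD (largest absolute deviation) and RMSD (root mean square
of the pooled deviations), both in percentage points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CARBON_LABELS",
    "PRODUCT_LABELS",
    "NO_CONTRIBUTION",
    "AccessibilityProfile",
    "ProductDistribution",
    "ComparisonStats",
    "map_stereo_labels",
    "snapshot_weights",
    "aggregate_trajectory",
    "apply_bisallylic_penalty",
    "average_replicates",
    "compare_distributions",
    "read_experimental_table",
    "predict_distribution",
]

CARBON_LABELS = ("C9", "C11", "C13")
PRODUCT_LABELS = ("9R", "11R", "13S")

_STEREO_MAP = dict(zip(CARBON_LABELS, PRODUCT_LABELS))

_FRACTION_TOL = 1e-9


class _NoContribution:
    """Sentinel: a snapshot whose three sites are all fully shielded is
    excluded from aggregation rather than counted as uniform."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover
        return "NO_CONTRIBUTION"


NO_CONTRIBUTION = _NoContribution()


@dataclass
class AccessibilityProfile:
    """Accessibility scores for (C9, C11, C13) of one snapshot, each in
    [0, 1]."""

    scores: tuple[float, float, float]
    snapshot_label: str = ""

    def __post_init__(self) -> None:
        if len(self.scores) != 3:
            raise ValueError("scores must be a (C9, C11, C13) triple")
        self.scores = tuple(float(s) for s in self.scores)
        for s in self.scores:
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"accessibility score {s} outside [0, 1]")


@dataclass
class ProductDistribution:
    """Fractions over the antarafacial products 9R/11R/13S (sum 1)."""

    fractions: dict[str, float]
    n_snapshots_contributing: int = 0

    def __post_init__(self) -> None:
        self.fractions = {k: float(v) for k, v in self.fractions.items()}
        for label, value in self.fractions.items():
            if value < -_FRACTION_TOL:
                raise ValueError(f"negative fraction for {label}: {value}")
        total = sum(self.fractions.values())
        if self.n_snapshots_contributing > 0 and abs(total - 1.0) > _FRACTION_TOL:
            raise ValueError(f"fractions sum to {total}, expected 1")

    def as_array(self, labels: Sequence[str] = PRODUCT_LABELS) -> np.ndarray:
        return np.array([self.fractions[label] for label in labels])


@dataclass
class ComparisonStats:
    """Pooled model-vs-experiment deviations in percentage points."""

    rmsd: float
    maxd: float
    per_product_deviations: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rmsd < 0 or self.maxd < 0:
            raise ValueError("rmsd and maxd must be non-negative")
        if self.maxd + 1e-12 < self.rmsd:
            raise ValueError("maxd cannot be smaller than rmsd")


def map_stereo_labels(carbon: str) -> str:
    """Antarafacial attack maps C9 -> 9R, C11 -> 11R, C13 -> 13S."""
    try:
        return _STEREO_MAP[carbon]
    except KeyError:
        raise ValueError(
            f"unknown reactive carbon {carbon!r}; expected one of {CARBON_LABELS}"
        ) from None


def snapshot_weights(profile: AccessibilityProfile):
    """Normalize one snapshot's accessibility triple to product weights;
    returns :data:`NO_CONTRIBUTION` when all three sites are shielded."""
    scores = np.asarray(profile.scores, dtype=float)
    total = scores.sum()
    if total == 0.0:
        return NO_CONTRIBUTION
    return scores / total


def aggregate_trajectory(
    profiles: Sequence[AccessibilityProfile],
) -> ProductDistribution:
    """Mean of per-snapshot weights over contributing snapshots,
    renormalized (raw distribution, before the bis-allylic penalty)."""
    if not profiles:
        raise ValueError("cannot aggregate an empty profile list")
    weights = []
    for profile in profiles:
        w = snapshot_weights(profile)
        if w is not NO_CONTRIBUTION:
            weights.append(w)
    if not weights:
        raise ValueError("no snapshot contributes: all sites shielded everywhere")
    mean = np.mean(weights, axis=0)
    mean = mean / mean.sum()
    return ProductDistribution(
        fractions={map_stereo_labels(c): float(v) for c, v in zip(CARBON_LABELS, mean)},
        n_snapshots_contributing=len(weights),
    )


def apply_bisallylic_penalty(
    dist: ProductDistribution,
    penalty: float = 0.10,
    mode: str = "relative",
) -> ProductDistribution:
    """Move part of the 11R fraction to 9R and 13S in equal halves.

    Oxygen attack at the central (bis-allylic) C11 carries a higher
    activation barrier than at the outer carbons; the penalty lowers the
    C11 product accordingly.  ``mode='relative'`` (default) removes
    ``penalty * fraction(11R)``; ``mode='absolute'`` removes ``penalty``
    percentage points of the total, clamped so 11R cannot go negative.
    """
    if not 0 <= penalty < 1:
        raise ValueError("penalty must be in [0, 1)")
    if mode not in ("relative", "absolute"):
        raise ValueError("mode must be 'relative' or 'absolute'")
    fractions = dict(dist.fractions)
    f11 = fractions.get("11R", 0.0)
    removed = penalty * f11 if mode == "relative" else min(penalty, f11)
    fractions["11R"] = f11 - removed
    fractions["9R"] = fractions.get("9R", 0.0) + removed / 2
    fractions["13S"] = fractions.get("13S", 0.0) + removed / 2
    return ProductDistribution(
        fractions=fractions,
        n_snapshots_contributing=dist.n_snapshots_contributing,
    )


def average_replicates(
    dists: Sequence[ProductDistribution],
) -> ProductDistribution:
    """Unweighted per-product mean over replicate runs, renormalized."""
    if not dists:
        raise ValueError("need at least one distribution")
    labels = tuple(dists[0].fractions)
    for d in dists[1:]:
        if tuple(d.fractions) != labels:
            raise ValueError("replicates carry different product label sets")
    stacked = np.array([[d.fractions[label] for label in labels] for d in dists])
    mean = stacked.mean(axis=0)
    mean = mean / mean.sum()
    return ProductDistribution(
        fractions=dict(zip(labels, mean.tolist())),
        n_snapshots_contributing=sum(d.n_snapshots_contributing for d in dists),
    )


def compare_distributions(
    simulated: Mapping[str, ProductDistribution],
    experimental: Mapping[str, Mapping[str, float]],
) -> ComparisonStats:
    """MAXD / RMSD between predicted and experimental product fractions.

    ``experimental`` maps enzyme -> {product label -> fraction}; fractions
    may be on the 0-1 or 0-100 scale and are renormalized over the
    9R/11R/13S trio.  Deviations are pooled over all (enzyme, product)
    pairs and reported in percentage points.
    """
    if set(simulated) != set(experimental):
        raise ValueError(
            f"enzyme sets differ: {sorted(simulated)} vs {sorted(experimental)}"
        )
    deviations: dict[tuple[str, str], float] = {}
    for enzyme, sim in simulated.items():
        exp = experimental[enzyme]
        if set(exp) != set(sim.fractions):
            raise ValueError(f"product labels differ for {enzyme}")
        total = sum(exp.values())
        if total <= 0:
            raise ValueError(f"experimental fractions for {enzyme} sum to {total}")
        for label in sim.fractions:
            sim_pct = 100.0 * sim.fractions[label]
            exp_pct = 100.0 * exp[label] / total
            deviations[(enzyme, label)] = sim_pct - exp_pct
    pooled = np.array(list(deviations.values()))
    return ComparisonStats(
        rmsd=float(np.sqrt(np.mean(pooled**2))),
        maxd=float(np.max(np.abs(pooled))),
        per_product_deviations=deviations,
    )


def read_experimental_table(path: str | Path) -> dict[str, dict[str, float]]:
    """Read experimental product fractions from a CSV with columns
    ``enzyme, product_label, fraction_percent`` and renormalize each enzyme
    over the 9R/11R/13S trio."""
    table = pd.read_csv(path)
    required = {"enzyme", "product_label", "fraction_percent"}
    if not required.issubset(table.columns):
        raise ValueError(f"experimental table needs columns {sorted(required)}")
    table = table[table["product_label"].isin(PRODUCT_LABELS)]
    out: dict[str, dict[str, float]] = {}
    for enzyme, group in table.groupby("enzyme"):
        values = dict(zip(group["product_label"], group["fraction_percent"]))
        missing = set(PRODUCT_LABELS) - set(values)
        if missing:
            raise ValueError(f"{enzyme}: missing products {sorted(missing)}")
        total = sum(values.values())
        out[str(enzyme)] = {k: v / total for k, v in values.items()}
    return out


def predict_distribution(
    profiles: Sequence[AccessibilityProfile],
    penalty: float = 0.10,
    mode: str = "relative",
) -> ProductDistribution:
    """Aggregate a trajectory's profiles and apply the bis-allylic penalty."""
    return apply_bisallylic_penalty(aggregate_trajectory(profiles), penalty, mode)
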