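"""Cortical hierarchy masks and cross-hierarchy contrasts.

Parcels are assigned to a higher-order cognitive region (default mode +
frontoparietal networks) or a lower-order sensory-motor region (somatomotor +
visual networks) by majority vertex overlap; per-parcel maps are then
summarized within and contrasted across the two regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "NETWORKS",
    "HIGHER_ORDER_NETWORKS",
    "LOWER_ORDER_NETWORKS",
    "Parcellation",
    "HierarchyMasks",
    "assign_hierarchy",
    "regional_mean",
    "cross_hierarchy_contrast",
]

NETWORKS = ("DMN", "FPN", "somatomotor", "visual", "other")
HIGHER_ORDER_NETWORKS = ("DMN", "FPN")
LOWER_ORDER_NETWORKS = ("somatomotor", "visual")


@dataclass
class Parcellation:
    """Parcel identities with principal-gradient values and network overlaps.

    Attributes
    ----------
    parcel_ids : list of str
    pg : (n_parcels,) array
        Principal-gradient value per parcel; low values sit at the
        sensory-motor end of the hierarchy, high values at the default-mode end.
    overlaps : DataFrame (n_parcels x networks)
        Fraction of each parcel's vertices overlapping each network; rows sum
        to at most 1 (exactly 1 when every vertex is assigned).
    """

    parcel_ids: list[str]
    pg: np.ndarray
    overlaps: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pg = np.asarray(self.pg, dtype=float)
        if len(self.parcel_ids) != self.pg.shape[0]:
            raise ValueError("pg length must match parcel count")
        if list(self.overlaps.index) != list(self.parcel_ids):
            self.overlaps = self.overlaps.reindex(self.parcel_ids)
        missing = [c for c in NETWORKS if c not in self.overlaps.columns]
        if missing:
            raise ValueError(f"overlap table missing networks: {missing}")

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_ids)

    def dominant_network(self) -> pd.Series:
        return self.overlaps[list(NETWORKS)].idxmax(axis=1)

    def pg_rank(self) -> np.ndarray:
        """0-based rank of each parcel along the principal gradient."""
        order = np.argsort(self.pg, kind="stable")
        ranks = np.empty_like(order)
        ranks[order] = np.arange(self.n_parcels)
        return ranks


@dataclass(frozen=True)
class HierarchyMasks:
    """Disjoint higher / lower / unassigned parcel ID sets covering a parcellation."""

    higher: frozenset[str]
    lower: frozenset[str]
    unassigned: frozenset[str]

    def __post_init__(self) -> None:
        if self.higher & self.lower or self.higher & self.unassigned or self.lower & self.unassigned:
            raise ValueError("hierarchy masks must be disjoint")


def assign_hierarchy(parcellation: Parcellation, threshold: float = 0.5) -> HierarchyMasks:
    """Classify each parcel by majority network overlap.

    A parcel is higher-order if strictly more than ``threshold`` of its
    vertices fall in DMN+FPN, lower-order if strictly more than ``threshold``
    fall in somatomotor+visual, and unassigned otherwise (including exact
    ties at the threshold).
    """
    ov = parcellation.overlaps
    sums = ov[list(NETWORKS)].sum(axis=1)
    bad = sums[sums > 1 + 1e-9]
    if len(bad):
        raise ValueError(
            f"overlap fractions exceed 1 for parcels: {list(bad.index)[:5]}"
        )
    higher_frac = ov[list(HIGHER_ORDER_NETWORKS)].sum(axis=1)
    lower_frac = ov[list(LOWER_ORDER_NETWORKS)].sum(axis=1)
    higher, lower, unassigned = set(), set(), set()
    for pid in parcellation.parcel_ids:
        if higher_frac[pid] > threshold:
            higher.add(pid)
        elif lower_frac[pid] > threshold:
            lower.add(pid)
        else:
            unassigned.add(pid)
    return HierarchyMasks(frozenset(higher), frozenset(lower), frozenset(unassigned))


def _as_map(per_parcel_map: Mapping[str, float] | pd.Series) -> pd.Series:
    if isinstance(per_parcel_map, pd.Series):
        return per_parcel_map
    return pd.Series(dict(per_parcel_map))


def regional_mean(per_parcel_map: Mapping[str, float] | pd.Series, mask: Iterable[str]) -> float:
    """Unweighted mean of a per-parcel map over the parcels in ``mask``."""
    series = _as_map(per_parcel_map)
    ids = list(mask)
    if not ids:
        raise ValueError("mask is empty")
    missing = [p for p in ids if p not in series.index]
    if missing:
        raise ValueError(f"map does not cover mask parcels: {missing[:5]}")
    return float(series.loc[ids].mean())


def cross_hierarchy_contrast(
    per_parcel_map: Mapping[str, float] | pd.Series, masks: HierarchyMasks
) -> float:
    """Higher-order mean minus lower-order mean of a per-parcel map."""
    return regional_mean(per_parcel_map, masks.higher) - regional_mean(
        per_parcel_map, masks.lower
    )
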