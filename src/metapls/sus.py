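"""Shared-and-unique-structure (SUS) comparison of two OPLS-DA models.

Two models fitted against the same reference class are overlaid by their
corr(t_p, X) profiles; metabolites near the diagonal are shared effects,
metabolites near an axis are unique to one model.  Proximity is quantified
angularly since no numeric rule is standard: the defaults (diagonal cone
20 deg, axis cone 15 deg, magnitude floor 0.3) are surfaced as parameters.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from metapls.markers import splot, vip
from metapls.opls import OplsModel

__all__ = [
    "SusPoint",
    "SusRegion",
    "SusClassification",
    "sus_profiles",
    "classify_shared_unique",
    "venn_counts",
]


class SusRegion(str, Enum):
    SHARED_POSITIVE = "shared_positive"
    SHARED_NEGATIVE = "shared_negative"
    UNIQUE_A = "unique_a"
    UNIQUE_B = "unique_b"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class SusPoint:
    """One metabolite's coordinates on the SUS plane (both axes in [-1, 1])."""

    metabolite: str
    corr_a: float
    corr_b: float
    vip_a: float
    vip_b: float


@dataclass(frozen=True)
class SusClassification:
    """Region assignment for every VIP-selected metabolite."""

    regions: dict[str, SusRegion]

    def members(self, region: SusRegion) -> list[str]:
        return sorted(m for m, r in self.regions.items() if r == region)


def _aligned_corr(model: OplsModel, X_centered: np.ndarray, reference: str):
    """corr/vip profile with sign flipped so the reference class scores negative."""
    labels = np.asarray(model.labels)
    if reference not in set(labels.tolist()):
        raise ValueError(f"reference class {reference!r} absent from model labels")
    flip = model.scores_pred[labels == reference].mean() > 0
    sign = -1.0 if flip else 1.0
    corr = {pt.variable: sign * pt.corr for pt in splot(model, X_centered)}
    vips = vip(model)
    names = model.var_names or tuple(f"var{j + 1}" for j in range(len(vips)))
    return corr, dict(zip(names, (float(v) for v in vips)))


def sus_profiles(
    model_a: OplsModel,
    model_b: OplsModel,
    X_a: np.ndarray,
    X_b: np.ndarray,
    reference: str,
) -> list[SusPoint]:
    """Overlay the corr(t_p, X) profiles of two models on shared metabolites.

    Both models must be fitted against the same reference class; signs are
    aligned so positive correlation means elevated in the non-reference
    class of each model.  Metabolites outside the intersection of the two
    variable sets are dropped; disjoint sets are an error.
    """
    corr_a, vip_a = _aligned_corr(model_a, X_a, reference)
    corr_b, vip_b = _aligned_corr(model_b, X_b, reference)
    names_a = model_a.var_names or tuple(corr_a)
    common = [m for m in names_a if m in corr_a and m in corr_b]
    if not common:
        raise ValueError("models share no metabolites")
    return [
        SusPoint(
            metabolite=m,
            corr_a=corr_a[m],
            corr_b=corr_b[m],
            vip_a=vip_a[m],
            vip_b=vip_b[m],
        )
        for m in common
    ]


def _angular_distance(theta: float, target: float) -> float:
    """Distance between two angles in degrees, folded to [0, 180]."""
    d = abs((theta - target) % 360.0)
    return min(d, 360.0 - d)


def _line_distance(theta: float, line_angle: float) -> float:
    """Angular distance from direction ``theta`` to the LINE at ``line_angle``."""
    return min(
        _angular_distance(theta, line_angle), _angular_distance(theta, line_angle + 180.0)
    )


def classify_shared_unique(
    points: Sequence[SusPoint],
    vip_cut: float = 1.0,
    axis_angle_deg: float = 15.0,
    diag_angle_deg: float = 20.0,
    magnitude_floor: float = 0.3,
) -> SusClassification:
    """Assign each VIP-selected metabolite to a SUS region.

    Only metabolites with ``max(vip_a, vip_b) > vip_cut`` are classified.
    With point angle ``theta = atan2(corr_b, corr_a)``:

    - within ``diag_angle_deg`` of the +45 deg line -> shared_positive;
    - within ``diag_angle_deg`` of the -45 deg line -> shared_negative;
    - within ``axis_angle_deg`` of the corr_a axis and |corr_a| above the
      magnitude floor -> unique_a (and symmetrically unique_b);
    - points with both correlations below the floor, or outside every cone,
      are unclassified.
    """
    if not 0 < axis_angle_deg < 45:
        raise ValueError("axis_angle_deg must be in (0, 45)")
    if not 0 < diag_angle_deg < 45:
        raise ValueError("diag_angle_deg must be in (0, 45)")
    regions: dict[str, SusRegion] = {}
    for pt in points:
        if max(pt.vip_a, pt.vip_b) <= vip_cut:
            continue
        regions[pt.metabolite] = _classify_point(
            pt.corr_a, pt.corr_b, axis_angle_deg, diag_angle_deg, magnitude_floor
        )
    return SusClassification(regions=regions)


def _classify_point(
    corr_a: float,
    corr_b: float,
    axis_angle_deg: float,
    diag_angle_deg: float,
    magnitude_floor: float,
) -> SusRegion:
    if abs(corr_a) < magnitude_floor and abs(corr_b) < magnitude_floor:
        return SusRegion.UNCLASSIFIED
    theta = math.degrees(math.atan2(corr_b, corr_a))
    if _line_distance(theta, 45.0) <= diag_angle_deg:
        return SusRegion.SHARED_POSITIVE
    if _line_distance(theta, -45.0) <= diag_angle_deg:
        return SusRegion.SHARED_NEGATIVE
    if _line_distance(theta, 0.0) <= axis_angle_deg and abs(corr_a) >= magnitude_floor:
        return SusRegion.UNIQUE_A
    if _line_distance(theta, 90.0) <= axis_angle_deg and abs(corr_b) >= magnitude_floor:
        return SusRegion.UNIQUE_B
    return SusRegion.UNCLASSIFIED


def venn_counts(classification: SusClassification) -> dict:
    """Per-region counts plus sorted membership lists."""
    out: dict = {"counts": {}, "members": {}}
    for region in SusRegion:
        members = classification.members(region)
        out["counts"][region.value] = len(members)
        out["members"][region.value] = members
    return out


def sus_table(points: Sequence[SusPoint], classification: SusClassification) -> pd.DataFrame:
    rows = []
    for pt in points:
        region = classification.regions.get(pt.metabolite)
        rows.append(
            {
                "metabolite": pt.metabolite,
                "corr_a": pt.corr_a,
                "corr_b": pt.corr_b,
                "vip_a": pt.vip_a,
                "vip_b": pt.vip_b,
                "region": region.value if region else "not_selected",
            }
        )
    return pd.DataFrame(rows)


def write_venn_json(classification: SusClassification, path) -> None:
    with open(path, "w") as fh:
        json.dump(venn_counts(classification), fh, indent=2, sort_keys=True)
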