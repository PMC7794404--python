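"""Glacial-refugia consensus maps and long-term stability areas.

A putative glacial refugium is any cell classified suitable at the glacial
maximum by at least ``min_agree`` of the palaeoclimate reconstructions
(GCMs).  A stability area is the overlap of (i) that glacial consensus,
(ii) the phylogeographically inferred ancestral area (a polygon), and
optionally (iii) current suitability — a proxy for persistent occupancy
across every time window with evidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import shape
from shapely.geometry.base import BaseGeometry

from .grid import BinaryMap, ConsensusMap, require_same_geometry

__all__ = ["AncestralArea", "gcm_consensus", "stability_areas"]


@dataclass
class AncestralArea:
    """Ancestral-area polygon from Bayesian phylogeography (an HPD contour)."""

    polygon: BaseGeometry
    lineage: str = ""
    hpd_level: float = 0.7

    def __post_init__(self):
        if isinstance(self.polygon, dict):
            self.polygon = shape(self.polygon)
        if self.polygon.is_empty:
            raise ValueError("ancestral-area polygon is empty")
        if not self.polygon.is_valid:
            raise ValueError("ancestral-area polygon is invalid (self-intersecting rings?)")


def gcm_consensus(binary_maps: list[BinaryMap], min_agree: int = 2) -> ConsensusMap:
    """Cell-wise consensus across per-GCM binary suitability maps.

    A cell is a putative refugium iff at least ``min_agree`` maps classify it
    suitable; the per-cell agreement count is kept alongside.
    """
    if not binary_maps:
        raise ValueError("no binary maps supplied")
    require_same_geometry(*binary_maps)
    stack = np.array([np.where(m.mask, m.values, 0.0) for m in binary_maps])
    agreement = stack.sum(axis=0).astype(int)
    valid = np.any([m.mask for m in binary_maps], axis=0)
    nodata = binary_maps[0].nodata
    vals = np.where(valid, (agreement >= min_agree).astype(float), nodata)
    return ConsensusMap(BinaryMap(binary_maps[0].geometry, vals, nodata=nodata), agreement)


def stability_areas(
    current: BinaryMap,
    refugia: ConsensusMap,
    ancestral: AncestralArea,
    include_current: bool = True,
) -> BinaryMap:
    """Overlap of glacial consensus, ancestral polygon and (optionally)
    current suitability.  Cell membership in the polygon is decided by the
    cell centre.  ``include_current=False`` reduces the definition to
    refugium-and-ancestral overlap.
    """
    require_same_geometry(current, refugia.binary)
    geom = current.geometry
    centers = geom.all_centers()
    # a point intersects the polygon iff it lies inside or on the boundary
    inside = shapely.intersects_xy(ancestral.polygon, centers[:, 0], centers[:, 1]).reshape(
        geom.rows, geom.cols
    )
    if not inside.any():
        warnings.warn("ancestral polygon does not cover any grid cell centre")
    stable = (refugia.binary.values == 1) & refugia.binary.mask & inside
    if include_current:
        stable &= (current.values == 1) & current.mask
    nodata = current.nodata
    valid = current.mask | refugia.binary.mask
    vals = np.where(valid, stable.astype(float), nodata)
    return BinaryMap(geom, vals, nodata=nodata)
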