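"""Hematoma segmentation, volumetry, expansion classification, and the
multihematoma fuzzy sign detector.

The sign is called when all three criteria hold:

c1  at least three hyperdense hematomas form an adjacency cluster, where
    two hematomas are adjacent if their nearest-surface separation does
    not exceed the largest diameter (3-D Feret) of the largest hematoma;
c2  the corridor between each adjacent pair has blood density — above the
    gray/white parenchyma band but below acute clot (a "fuzzy" signal,
    not normal brain);
c3  the clot-minus-corridor contrast is at least 20 HU for each adjacent
    pair.

c2/c3 quantify over the adjacent pairs of the largest cluster and hold
vacuously when no pair is adjacent, so a scan that fails only the count
or distance rule reports c1=False with c2=c3=True.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree, ConvexHull, QhullError

from .volume import CTVolume

_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class SegmentationConfig:
    """Thresholds for HU-based hematoma segmentation and sign detection."""

    clot_threshold_hu: float = 50.0
    parenchyma_band_hu: tuple[float, float] = (20.0, 40.0)
    min_component_ml: float = 0.1
    connectivity: int = 26
    contrast_rule_hu: float = 20.0
    corridor_radius_voxels: float = 2.0

    def __post_init__(self):
        if self.clot_threshold_hu <= self.parenchyma_band_hu[1]:
            raise ValueError(
                "clot threshold must exceed the parenchyma band"
            )
        if self.min_component_ml <= 0:
            raise ValueError("min_component_ml must be positive")
        if self.connectivity not in _STRUCTS:
            raise ValueError("connectivity must be 6, 18 or 26")


@dataclass
class HematomaComponent:
    """One connected hyperdense blob found by segmentation."""

    label: int
    voxel_indices: np.ndarray  # (n, 3) int array
    volume_ml: float
    mean_hu: float
    centroid_mm: tuple[float, float, float]
    feret_diameter_mm: float


@dataclass
class SignEvidence:
    """Full audit record of a fuzzy-sign evaluation."""

    n_components: int
    involved_component_ids: list[int]
    pairwise_separation_mm: list[list[float]]
    d_max_mm: float
    bridge_mean_hu: dict
    clot_minus_bridge_hu: dict
    c1: bool
    c2: bool
    c3: bool
    sign: bool

    def to_json(self) -> str:
        d = asdict(self)
        d["bridge_mean_hu"] = {
            f"{i}-{j}": v for (i, j), v in self.bridge_mean_hu.items()
        }
        d["clot_minus_bridge_hu"] = {
            f"{i}-{j}": v for (i, j), v in self.clot_minus_bridge_hu.items()
        }
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class ExpansionCall:
    """Outcome of the hematoma growth rule (>=30% relative or >=5 mL)."""

    baseline_ml: float
    followup_ml: float
    relative_growth: float = field(init=False)
    absolute_growth_ml: float = field(init=False)
    expanded: bool = field(init=False)

    def __post_init__(self):
        if self.baseline_ml <= 0:
            raise ValueError("baseline volume must be positive")
        self.absolute_growth_ml = self.followup_ml - self.baseline_ml
        self.relative_growth = self.absolute_growth_ml / self.baseline_ml
        self.expanded = (
            self.relative_growth >= 0.30 or self.absolute_growth_ml >= 5.0
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


# ----------------------------------------------------------- segmentation


def _surface_indices(mask_indices: np.ndarray, shape) -> np.ndarray:
    """Boundary voxels of a component (6-neighborhood erosion residue)."""
    mins = mask_indices.min(axis=0)
    maxs = mask_indices.max(axis=0)
    local = np.zeros(maxs - mins + 3, dtype=bool)
    local[tuple((mask_indices - mins + 1).T)] = True
    interior = ndimage.binary_erosion(
        local, structure=ndimage.generate_binary_structure(3, 1)
    )
    surf = np.argwhere(local & ~interior) + mins - 1
    return surf


def _feret_diameter_mm(surface_mm: np.ndarray) -> float:
    """Largest boundary-to-boundary distance, via the convex hull."""
    pts = surface_mm
    if len(pts) > 8:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except QhullError:
            pass  # degenerate (coplanar) point sets: brute force below
    if len(pts) > 2000:
        pts = pts[:: len(pts) // 2000 + 1]
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def segment_hematomas(
    vol: CTVolume, cfg: SegmentationConfig | None = None
) -> list[HematomaComponent]:
    """Threshold-and-label segmentation of hyperdense hematomas.

    Connected voxel sets with HU >= ``clot_threshold_hu`` (26-neighborhood
    by default), filtered to at least ``min_component_ml``, sorted by
    descending volume.  Returns an empty list when nothing is above
    threshold.
    """
    cfg = cfg or SegmentationConfig()
    if vol.voxels.size == 0 or not np.isfinite(vol.voxels).all():
        raise ValueError("degenerate volume")
    mask = vol.voxels >= cfg.clot_threshold_hu
    labels, n = ndimage.label(mask, structure=_STRUCTS[cfg.connectivity])
    if n == 0:
        return []
    vox_ml = vol.voxel_volume_ml
    counts = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero(counts * vox_ml >= cfg.min_component_ml) + 1
    comps = []
    spacing = np.asarray(vol.spacing_mm)
    for lab in keep:
        idx = np.argwhere(labels == lab)
        centers = (idx + 0.5) * spacing
        surf = _surface_indices(idx, vol.shape)
        feret = _feret_diameter_mm((surf + 0.5) * spacing)
        comps.append(
            HematomaComponent(
                label=int(lab),
                voxel_indices=idx,
                volume_ml=float(len(idx) * vox_ml),
                mean_hu=float(vol.voxels[tuple(idx.T)].mean()),
                centroid_mm=tuple(centers.mean(axis=0)),
                feret_diameter_mm=feret,
            )
        )
    comps.sort(key=lambda c: (-c.volume_ml, -c.mean_hu, c.label))
    return comps


def total_hematoma_volume(components: list[HematomaComponent]) -> float:
    """Total hematoma burden of a scan: the sum over all components."""
    return float(sum(c.volume_ml for c in components))


# --------------------------------------------------------------- detector


def _check_components_in_bounds(vol, components):
    for c in components:
        if len(c.voxel_indices) == 0:
            raise ValueError("component with empty voxel set")
        if (c.voxel_indices < 0).any() or (
            c.voxel_indices >= np.asarray(vol.shape)
        ).any():
            raise ValueError("component voxels outside the volume")


def _corridor_mean_hu(vol, p0, p1, component_mask, radius_mm):
    """Mean HU of voxels near the segment p0-p1, excluding hematoma
    voxels.  The radius is grown geometrically if the corridor is empty
    (very tight gaps)."""
    spacing = np.asarray(vol.spacing_mm)
    lo = np.minimum(p0, p1) - 4 * radius_mm
    hi = np.maximum(p0, p1) + 4 * radius_mm
    lo_idx = np.maximum((lo / spacing - 1).astype(int), 0)
    hi_idx = np.minimum(
        (hi / spacing + 2).astype(int), np.asarray(vol.shape)
    )
    sl = tuple(slice(a, b) for a, b in zip(lo_idx, hi_idx))
    idx = np.argwhere(~component_mask[sl]) + lo_idx
    if len(idx) == 0:
        return float("nan")
    centers = (idx + 0.5) * spacing
    v = np.asarray(p1) - np.asarray(p0)
    L2 = float(v @ v)
    diff = centers - np.asarray(p0)
    if L2 == 0.0:
        dist2 = (diff**2).sum(axis=1)
    else:
        t = np.clip(diff @ v / L2, 0.0, 1.0)
        dist2 = ((diff - t[:, None] * v) ** 2).sum(axis=1)
    r = radius_mm
    for _ in range(6):
        inside = dist2 <= r**2
        if inside.any():
            hu = vol.voxels[tuple(idx[inside].T)]
            return float(hu.mean())
        r *= 1.5
    return float("nan")


def detect_fuzzy_sign(
    vol: CTVolume,
    components: list[HematomaComponent],
    cfg: SegmentationConfig | None = None,
) -> SignEvidence:
    """Evaluate the three multihematoma fuzzy sign criteria on a scan."""
    cfg = cfg or SegmentationConfig()
    _check_components_in_bounds(vol, components)
    n = len(components)
    spacing = np.asarray(vol.spacing_mm)

    if n == 0:
        return SignEvidence(
            n_components=0,
            involved_component_ids=[],
            pairwise_separation_mm=[],
            d_max_mm=0.0,
            bridge_mean_hu={},
            clot_minus_bridge_hu={},
            c1=False,
            c2=True,
            c3=True,
            sign=False,
        )

    surfaces = [
        (_surface_indices(c.voxel_indices, vol.shape) + 0.5) * spacing
        for c in components
    ]
    trees = [cKDTree(s) for s in surfaces]

    sep = np.zeros((n, n))
    nearest_pts: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d, jj = trees[j].query(surfaces[i])
            k = int(np.argmin(d))
            sep[i, j] = sep[j, i] = float(d[k])
            nearest_pts[(i, j)] = (surfaces[i][k], surfaces[j][jj[k]])

    # components are sorted by (volume desc, mean HU desc, label):
    # index 0 is the largest hematoma with the spec'd tie-break
    d_max = components[0].feret_diameter_mm

    adj = sep <= d_max
    np.fill_diagonal(adj, False)
    unvisited = set(range(n))
    clusters = []
    while unvisited:
        stack = [unvisited.pop()]
        comp = set(stack)
        while stack:
            u = stack.pop()
            for w in list(unvisited):
                if adj[u, w]:
                    unvisited.remove(w)
                    comp.add(w)
                    stack.append(w)
        clusters.append(comp)
    cluster = max(clusters, key=lambda c: (len(c), -min(c)))
    c1 = len(cluster) >= 3

    component_mask = np.zeros(vol.shape, dtype=bool)
    for c in components:
        component_mask[tuple(c.voxel_indices.T)] = True

    radius_mm = cfg.corridor_radius_voxels * float(np.min(spacing))
    pairs = [
        (i, j)
        for i in sorted(cluster)
        for j in sorted(cluster)
        if i < j and adj[i, j]
    ]
    bridge_hu: dict[tuple[int, int], float] = {}
    contrast: dict[tuple[int, int], float] = {}
    c2, c3 = True, True
    for i, j in pairs:
        p0, p1 = nearest_pts[(i, j)]
        hu = _corridor_mean_hu(vol, p0, p1, component_mask, radius_mm)
        bridge_hu[(i, j)] = hu
        pair_clot = 0.5 * (components[i].mean_hu + components[j].mean_hu)
        contrast[(i, j)] = pair_clot - hu
        if not (
            cfg.parenchyma_band_hu[1] < hu < cfg.clot_threshold_hu
        ) or not np.isfinite(hu):
            c2 = False
        if not contrast[(i, j)] >= cfg.contrast_rule_hu:
            c3 = False

    return SignEvidence(
        n_components=n,
        involved_component_ids=sorted(cluster) if c1 else [],
        pairwise_separation_mm=sep.tolist(),
        d_max_mm=float(d_max),
        bridge_mean_hu=bridge_hu,
        clot_minus_bridge_hu=contrast,
        c1=c1,
        c2=c2,
        c3=c3,
        sign=bool(c1 and c2 and c3),
    )


def classify_expansion(baseline_ml: float, followup_ml: float) -> ExpansionCall:
    """Apply the acute expansion rule: relative growth >= 30% or absolute
    growth >= 5 mL from baseline (both thresholds inclusive)."""
    return ExpansionCall(baseline_ml=float(baseline_ml), followup_ml=float(followup_ml))
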