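"""Ground-truthed synthetic CT phantoms of contusion hematomas.

Each phantom is a noisy parenchyma-density background (about 33 HU) into
which ellipsoidal acute-clot blobs (hyperdense, 50-90 HU) and optional
"fuzzy" blood-density corridors (40-50 HU) between blob pairs are
rasterized.  Six scenario families cover the positive geometry of the
multihematoma fuzzy sign and one designed failure per criterion:

``positive``             three adjacent clots bridged by blood-density fuzz
``two_blobs``            identical densities but only two clots (fails c1)
``far_apart``            three clots separated beyond the adjacency limit
                         (fails c1)
``low_contrast_bridge``  bridged clots whose clot-fuzz contrast is < 20 HU
                         (fails c3)
``parenchyma_gap``       adjacent clots separated by plain gray/white
                         matter (fails c2)
``single_blob``          one clot (fails c1)

Every phantom carries analytic ground truth (voxel masks, ellipsoid
volumes, per-criterion expectations) so the detector and volumetry can be
validated without any real imaging data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .volume import CTVolume, DEFAULT_SPACING_MM

SCENARIOS = (
    "positive",
    "two_blobs",
    "far_apart",
    "low_contrast_bridge",
    "parenchyma_gap",
    "single_blob",
)

# density regimes (HU)
BACKGROUND_HU = 33.0
BACKGROUND_NOISE_SD = 3.0
PARENCHYMA_HIGH_HU = 40.0  # upper edge of the gray/white band
CLOT_THRESHOLD_HU = 50.0  # lower edge of acute clot
CLOT_MAX_HU = 90.0
CONTRAST_RULE_HU = 20.0  # clot minus fuzz must reach this for the sign


@dataclass
class Blob:
    """Axis-aligned ellipsoid of acute clot."""

    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    mean_hu: float

    @property
    def analytic_volume_ml(self) -> float:
        r1, r2, r3 = self.radii_mm
        return 4.0 / 3.0 * np.pi * r1 * r2 * r3 / 1000.0

    @property
    def max_diameter_mm(self) -> float:
        return 2.0 * max(self.radii_mm)


@dataclass
class Bridge:
    """Cylindrical blood-density corridor joining the nearest surfaces of
    a blob pair."""

    pair: tuple[int, int]
    radius_mm: float
    mean_hu: float


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (160, 160, 16)
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING_MM
    background_hu: float = BACKGROUND_HU
    background_noise_sd: float = BACKGROUND_NOISE_SD
    blobs: list[Blob] = field(default_factory=list)
    bridges: list[Bridge] = field(default_factory=list)
    scenario_label: str = "positive"

    def validate(self) -> None:
        if self.scenario_label not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario_label!r}")
        if not self.blobs:
            raise ValueError("spec has no blobs")
        for b in self.blobs:
            if not (CLOT_THRESHOLD_HU <= b.mean_hu <= CLOT_MAX_HU):
                raise ValueError(
                    f"blob mean {b.mean_hu} HU outside acute clot range "
                    f"[{CLOT_THRESHOLD_HU}, {CLOT_MAX_HU}]"
                )
            if any(r <= 0 for r in b.radii_mm):
                raise ValueError("blob radii must be positive")
        min_blob = min(b.mean_hu for b in self.blobs)
        for br in self.bridges:
            i, j = br.pair
            if not (0 <= i < len(self.blobs) and 0 <= j < len(self.blobs)):
                raise ValueError(f"bridge pair {br.pair} out of range")
            if br.mean_hu >= min_blob:
                raise ValueError(
                    "bridge density must be below every blob density"
                )

    def to_json(self) -> str:
        return json.dumps(
            {
                "shape": list(self.shape),
                "spacing_mm": list(self.spacing_mm),
                "background_hu": self.background_hu,
                "background_noise_sd": self.background_noise_sd,
                "blobs": [
                    {
                        "center_mm": list(b.center_mm),
                        "radii_mm": list(b.radii_mm),
                        "mean_hu": b.mean_hu,
                    }
                    for b in self.blobs
                ],
                "bridges": [
                    {
                        "pair": list(br.pair),
                        "radius_mm": br.radius_mm,
                        "mean_hu": br.mean_hu,
                    }
                    for br in self.bridges
                ],
                "scenario_label": self.scenario_label,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        d = json.loads(text)
        return cls(
            shape=tuple(d["shape"]),
            spacing_mm=tuple(d["spacing_mm"]),
            background_hu=d["background_hu"],
            background_noise_sd=d["background_noise_sd"],
            blobs=[
                Blob(tuple(b["center_mm"]), tuple(b["radii_mm"]), b["mean_hu"])
                for b in d["blobs"]
            ],
            bridges=[
                Bridge(tuple(b["pair"]), b["radius_mm"], b["mean_hu"])
                for b in d["bridges"]
            ],
            scenario_label=d["scenario_label"],
        )


@dataclass
class PhantomTruth:
    """Analytic ground truth accompanying a generated phantom."""

    blob_masks: list[np.ndarray]
    bridge_masks: list[np.ndarray]
    analytic_volumes_ml: list[float]
    expected_sign: bool
    expected_criteria: tuple[bool, bool, bool]
    scenario_label: str

    def label_map(self) -> np.ndarray:
        """Blob masks as one integer label volume (1-based labels)."""
        lab = np.zeros(self.blob_masks[0].shape, dtype=np.int16)
        for k, m in enumerate(self.blob_masks, start=1):
            lab[m] = k
        return lab


# --------------------------------------------------------------- geometry


def _voxel_center_grids(shape, spacing):
    axes = [
        (np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)
    ]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _rasterize_ellipsoid(shape, spacing, blob: Blob) -> np.ndarray:
    cx, cy, cz = blob.center_mm
    rx, ry, rz = blob.radii_mm
    X, Y, Z = _voxel_center_grids(shape, spacing)
    q = (
        ((X - cx) / rx) ** 2
        + ((Y - cy) / ry) ** 2
        + ((Z - cz) / rz) ** 2
    )
    return q <= 1.0


def _mask_centers_mm(mask, spacing):
    idx = np.argwhere(mask)
    return (idx + 0.5) * np.asarray(spacing)


def _nearest_surface_points(mask_a, mask_b, spacing):
    """Nearest pair of voxel centers between two masks, with distance."""
    pa = _mask_centers_mm(mask_a, spacing)
    pb = _mask_centers_mm(mask_b, spacing)
    tree = cKDTree(pb)
    d, j = tree.query(pa)
    i = int(np.argmin(d))
    return pa[i], pb[j[i]], float(d[i])


def _rasterize_corridor(shape, spacing, p0, p1, radius_mm, exclude):
    """Voxels within ``radius_mm`` of segment p0-p1, minus ``exclude``."""
    X, Y, Z = _voxel_center_grids(shape, spacing)
    v = np.asarray(p1, dtype=float) - np.asarray(p0, dtype=float)
    L2 = float(v @ v)
    dx, dy, dz = X - p0[0], Y - p0[1], Z - p0[2]
    if L2 == 0.0:
        dist2 = dx**2 + dy**2 + dz**2
    else:
        t = (dx * v[0] + dy * v[1] + dz * v[2]) / L2
        t = np.clip(t, -0.05, 1.05)
        dist2 = (dx - t * v[0]) ** 2 + (dy - t * v[1]) ** 2 + (dz - t * v[2]) ** 2
    return (dist2 <= radius_mm**2) & ~exclude


# ------------------------------------------------------ expected criteria


def _expected_criteria(spec: PhantomSpec, blob_masks, spacing):
    """Derive the three sign criteria from the designed geometry.

    c2/c3 are universally quantified over the adjacent pairs of the
    largest adjacency cluster; with no adjacent pair they hold vacuously,
    so each negative scenario fails exactly its designed criterion.
    """
    n = len(spec.blobs)
    largest = max(range(n), key=lambda k: spec.blobs[k].analytic_volume_ml)
    d_max = spec.blobs[largest].max_diameter_mm

    gaps = np.full((n, n), np.inf)
    for i in range(n):
        for j in range(i + 1, n):
            _, _, g = _nearest_surface_points(
                blob_masks[i], blob_masks[j], spacing
            )
            gaps[i, j] = gaps[j, i] = g

    # connected components of the adjacency graph (edges: gap <= d_max)
    adj = gaps <= d_max
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
    cluster = max(clusters, key=len)
    c1 = len(cluster) >= 3

    bridge_by_pair = {tuple(sorted(b.pair)): b.mean_hu for b in spec.bridges}
    pairs = [
        (i, j)
        for i in sorted(cluster)
        for j in sorted(cluster)
        if i < j and adj[i, j]
    ]
    c2, c3 = True, True
    for i, j in pairs:
        corridor_hu = bridge_by_pair.get((i, j), spec.background_hu)
        pair_clot_hu = 0.5 * (spec.blobs[i].mean_hu + spec.blobs[j].mean_hu)
        if not (PARENCHYMA_HIGH_HU < corridor_hu < CLOT_THRESHOLD_HU):
            c2 = False
        if pair_clot_hu - corridor_hu < CONTRAST_RULE_HU:
            c3 = False
    return c1, c2, c3


_EXPECTED_BY_SCENARIO = {
    "positive": (True, True, True),
    "two_blobs": (False, True, True),
    "far_apart": (False, True, True),
    "low_contrast_bridge": (True, True, False),
    "parenchyma_gap": (True, False, True),
    "single_blob": (False, True, True),
}


# ---------------------------------------------------------------- builder


def generate_phantom(spec: PhantomSpec, seed: int) -> tuple[CTVolume, PhantomTruth]:
    """Rasterize a phantom spec into a noisy CT volume plus ground truth.

    The same ``(spec, seed)`` always produces a bit-identical volume.
    Raises ``ValueError`` for overlapping blobs or blobs extending past
    the volume bounds.
    """
    spec.validate()
    shape, spacing = tuple(spec.shape), tuple(spec.spacing_mm)
    extent = [n * s for n, s in zip(shape, spacing)]
    for b in spec.blobs:
        for c, r, e, s in zip(b.center_mm, b.radii_mm, extent, spacing):
            if c - r < s or c + r > e - s:
                raise ValueError(
                    f"blob at {b.center_mm} with radii {b.radii_mm} "
                    "extends outside the volume"
                )

    blob_masks = [_rasterize_ellipsoid(shape, spacing, b) for b in spec.blobs]
    any_blob = np.zeros(shape, dtype=bool)
    for k, m in enumerate(blob_masks):
        if (any_blob & m).any():
            raise ValueError(f"blob {k} overlaps an earlier blob")
        any_blob |= m

    bridge_masks = []
    for br in spec.bridges:
        i, j = br.pair
        p0, p1, _ = _nearest_surface_points(
            blob_masks[i], blob_masks[j], spacing
        )
        bridge_masks.append(
            _rasterize_corridor(shape, spacing, p0, p1, br.radius_mm, any_blob)
        )

    rng = np.random.default_rng(seed)
    hu = spec.background_hu + rng.normal(
        0.0, spec.background_noise_sd, size=shape
    )
    fuzz_covered = np.zeros(shape, dtype=bool)
    for br, m in zip(spec.bridges, bridge_masks):
        new = m & ~fuzz_covered  # overlapping corridors keep the first HU
        hu[new] = br.mean_hu + (hu[new] - spec.background_hu)
        fuzz_covered |= m
    for b, m in zip(spec.blobs, blob_masks):
        hu[m] = b.mean_hu + (hu[m] - spec.background_hu)

    criteria = _expected_criteria(spec, blob_masks, spacing)
    expected = _EXPECTED_BY_SCENARIO[spec.scenario_label]
    if criteria != expected:
        raise ValueError(
            f"scenario {spec.scenario_label!r} geometry yields criteria "
            f"{criteria}, expected {expected}"
        )

    truth = PhantomTruth(
        blob_masks=blob_masks,
        bridge_masks=bridge_masks,
        analytic_volumes_ml=[b.analytic_volume_ml for b in spec.blobs],
        expected_sign=all(criteria),
        expected_criteria=criteria,
        scenario_label=spec.scenario_label,
    )
    return CTVolume(hu, spacing_mm=spacing), truth


# ------------------------------------------------------ scenario sampling

_SHAPE = (160, 160, 16)
_CENTER_XY = 40.0
_Z_SLICE_CENTER = 37.5  # snapped to a 5 mm slice center
_BRIDGE_RADIUS_MM = 4.5
_FUZZ_HU_RANGE = (43.0, 45.0)


def _cluster_spec(rng, n_blobs, fuzz_hu_offset, with_bridges, label):
    """Shared builder for the adjacent-cluster scenarios.

    Blobs are laid out as a gently bent chain along a random direction
    (the contusion-track geometry); every pair is bridged when bridges
    are requested, so each corridor the detector samples is genuinely
    blood-density fuzz.
    """
    r_xy = rng.uniform(7.0, 9.0, size=n_blobs)
    r_z = rng.uniform(13.0, 16.0, size=n_blobs)
    fuzz_hu = rng.uniform(*_FUZZ_HU_RANGE)
    blob_hu = fuzz_hu + rng.uniform(*fuzz_hu_offset, size=n_blobs)

    pairs = [(i, j) for i in range(n_blobs) for j in range(i + 1, n_blobs)]
    gaps = [rng.uniform(4.5, 7.0) for _ in range(n_blobs - 1)]
    s = [0.0]
    for k in range(n_blobs - 1):
        s.append(s[-1] + r_xy[k] + gaps[k] + r_xy[k + 1])
    theta = rng.uniform(0, 2 * np.pi)
    u = np.array([np.cos(theta), np.sin(theta)])
    perp = np.array([-u[1], u[0]])
    xy = np.array([sk * u for sk in s])
    if n_blobs == 3:
        xy[1] = xy[1] + rng.uniform(0.0, 2.5) * perp  # slight bend
    xy += _CENTER_XY - xy.mean(axis=0) + rng.uniform(-2, 2, size=2)

    blobs = [
        Blob(
            center_mm=(xy[k][0], xy[k][1], _Z_SLICE_CENTER),
            radii_mm=(r_xy[k], r_xy[k], r_z[k]),
            mean_hu=float(blob_hu[k]),
        )
        for k in range(n_blobs)
    ]
    bridges = (
        [Bridge(p, _BRIDGE_RADIUS_MM, float(fuzz_hu)) for p in pairs]
        if with_bridges
        else []
    )
    return PhantomSpec(
        shape=_SHAPE, blobs=blobs, bridges=bridges, scenario_label=label
    )


def make_scenario_spec(scenario: str, rng: np.random.Generator) -> PhantomSpec:
    """Draw a randomized phantom spec within one scenario's constraints."""
    if scenario == "positive":
        return _cluster_spec(rng, 3, (23.0, 27.0), True, scenario)
    if scenario == "two_blobs":
        return _cluster_spec(rng, 2, (23.0, 27.0), True, scenario)
    if scenario == "low_contrast_bridge":
        return _cluster_spec(rng, 3, (13.0, 17.0), True, scenario)
    if scenario == "parenchyma_gap":
        spec = _cluster_spec(rng, 3, (23.0, 27.0), False, scenario)
        return spec
    if scenario == "single_blob":
        blobs = [
            Blob(
                center_mm=(
                    _CENTER_XY + rng.uniform(-3, 3),
                    _CENTER_XY + rng.uniform(-3, 3),
                    _Z_SLICE_CENTER,
                ),
                radii_mm=(
                    rng.uniform(7, 10),
                    rng.uniform(7, 10),
                    rng.uniform(13, 16),
                ),
                mean_hu=float(rng.uniform(60, 75)),
            )
        ]
        return PhantomSpec(shape=_SHAPE, blobs=blobs, scenario_label=scenario)
    if scenario == "far_apart":
        anchors = np.array([[18.0, 18.0], [62.0, 18.0], [40.0, 63.0]])
        blobs = []
        for a in anchors:
            c = a + rng.uniform(-1, 1, size=2)
            blobs.append(
                Blob(
                    center_mm=(c[0], c[1], _Z_SLICE_CENTER),
                    radii_mm=(
                        rng.uniform(5.5, 6.5),
                        rng.uniform(5.5, 6.5),
                        rng.uniform(10.0, 12.0),
                    ),
                    mean_hu=float(rng.uniform(63, 70)),
                )
            )
        return PhantomSpec(shape=_SHAPE, blobs=blobs, scenario_label=scenario)
    raise ValueError(f"unknown scenario {scenario!r}")


def generate_phantom_suite(
    n_per_scenario: int, seed: int
) -> list[tuple[CTVolume, PhantomTruth]]:
    """Generate ``n_per_scenario`` phantoms for each of the six scenarios.

    Deterministic under ``seed``; covers every scenario label in the fixed
    order of :data:`SCENARIOS`.
    """
    if n_per_scenario < 1:
        raise ValueError("n_per_scenario must be >= 1")
    out = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(SCENARIOS) * n_per_scenario)
    k = 0
    for scenario in SCENARIOS:
        for _ in range(n_per_scenario):
            child = children[k]
            k += 1
            rng = np.random.default_rng(child)
            spec = make_scenario_spec(scenario, rng)
            raster_seed = int(child.generate_state(1)[0] % (2**31))
            out.append(generate_phantom(spec, raster_seed))
    return out
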