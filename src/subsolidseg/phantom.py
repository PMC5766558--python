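"""Synthetic CT phantoms of subsolid nodules with voxel-level ground truth.

A phantom emulates the appearance the classifier must learn: lung parenchyma
around -900 HU, a hazy ground-glass ellipsoid around -600 HU, and soft-tissue
structures around +50 HU — tubular vessels swept along spline paths with a
tapering diameter profile, and an optional solid-core blob.  The geometry is
rasterized on an anisotropic source grid, blurred (partial-volume effect,
Gaussian sigma 0.6 mm) and corrupted with additive Gaussian noise (sigma
20 HU); everything is deterministic under the spec's seed.

Ground-truth labels are assigned on the *pre-blur* geometry (a partial-volume
voxel inherits the geometric class, mirroring how a human outlines
structures) with precedence core > vessel > ground-glass inside the nodule.
The outside part of every vessel is returned as a separate binary mask, so
the continuity analysis can be exercised without an external vessel
segmenter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, ndimage, spatial

from .volume import CORE, GROUND_GLASS, VESSEL, LabelMap, Volume

DEFAULT_SHAPE = (40, 56, 56)
DEFAULT_SPACING = (1.0, 0.7, 0.7)  # mm, (z, y, x): near-isotropic low-dose CT
DEFAULT_BACKGROUND_HU = -900.0
DEFAULT_GGO_HU = -600.0
DEFAULT_SOFT_HU = 50.0
DEFAULT_BLUR_SIGMA_MM = 0.6
DEFAULT_NOISE_SIGMA_HU = 20.0


@dataclass
class VesselSpec:
    """A tube swept along spline control points with a diameter profile."""

    points: list  # control points in mm, (z, y, x)
    diameters: list  # diameter (mm) at each control point
    hu: float = DEFAULT_SOFT_HU
    crossing: bool = True  # whether the path exits the nodule

    def __post_init__(self) -> None:
        self.points = [tuple(float(c) for c in p) for p in self.points]
        self.diameters = [float(d) for d in self.diameters]
        if len(self.points) < 2:
            raise ValueError("a vessel path needs at least two control points")
        if len(self.diameters) != len(self.points):
            raise ValueError("need one diameter per control point")
        if any(d <= 0 for d in self.diameters):
            raise ValueError("vessel diameters must be positive")


@dataclass
class CoreSpec:
    """A spherical solid-core blob."""

    center: tuple  # mm, (z, y, x)
    radius: float  # mm
    hu: float = DEFAULT_SOFT_HU


@dataclass
class PhantomSpec:
    """Full description of one synthetic subsolid nodule scene."""

    shape: tuple = DEFAULT_SHAPE
    spacing: tuple = DEFAULT_SPACING
    background_hu: float = DEFAULT_BACKGROUND_HU
    nodule_center: tuple | None = None  # mm; default: grid centre
    nodule_radii: tuple = (7.0, 7.0, 7.0)  # mm per axis
    ggo_hu: float = DEFAULT_GGO_HU
    core: CoreSpec | None = None
    vessels: list = field(default_factory=list)
    blur_sigma_mm: float = DEFAULT_BLUR_SIGMA_MM
    noise_sigma_hu: float = DEFAULT_NOISE_SIGMA_HU
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.core, dict):
            self.core = CoreSpec(**self.core)
        self.vessels = [
            VesselSpec(**v) if isinstance(v, dict) else v for v in self.vessels
        ]
        if self.nodule_center is None:
            self.nodule_center = tuple(
                (n - 1) * s / 2.0 for n, s in zip(self.shape, self.spacing)
            )
        soft = [v.hu for v in self.vessels] + ([self.core.hu] if self.core else [])
        if any(h <= self.ggo_hu for h in soft):
            raise ValueError("vessel/core HU must be strictly above ground-glass HU")
        if self.ggo_hu <= self.background_hu:
            raise ValueError("ground-glass HU must be strictly above background HU")


@dataclass
class PhantomBundle:
    """One generated phantom: image, masks, truth, and the sampled spec."""

    volume: Volume
    nodule: LabelMap  # binary
    truth: LabelMap  # 0/1/2/3 inside the nodule
    outer_vessels: LabelMap  # binary, vessel geometry outside the nodule
    spec: PhantomSpec


def _coord_grids(shape, spacing):
    return np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
    )


def _ellipsoid_mask(shape, spacing, center, radii) -> np.ndarray:
    zz, yy, xx = _coord_grids(shape, spacing)
    return (
        ((zz - center[0]) / radii[0]) ** 2
        + ((yy - center[1]) / radii[1]) ** 2
        + ((xx - center[2]) / radii[2]) ** 2
    ) <= 1.0


def _inside_ellipsoid(point, center, radii) -> bool:
    return sum(((p - c) / r) ** 2 for p, c, r in zip(point, center, radii)) <= 1.0


def _rasterize_vessel(vessel: VesselSpec, shape, spacing) -> np.ndarray:
    """Binary tube mask: voxels within the local radius of the swept path."""
    pts = np.asarray(vessel.points)
    dia = np.asarray(vessel.diameters)
    # arc-length parametrization, sampled finely relative to the grid
    seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(seglen)])
    if t[-1] <= 0:
        raise ValueError("vessel path has zero length")
    n_dense = max(int(t[-1] / (0.2 * min(spacing))), 2)
    td = np.linspace(0.0, t[-1], n_dense)
    if len(pts) > 2:
        path = np.column_stack(
            [interpolate.CubicSpline(t, pts[:, ax])(td) for ax in range(3)]
        )
    else:
        path = np.column_stack([np.interp(td, t, pts[:, ax]) for ax in range(3)])
    radii = np.interp(td, t, dia) / 2.0

    rmax = radii.max()
    lo = np.maximum(np.floor((path.min(axis=0) - rmax) / spacing).astype(int), 0)
    hi = np.minimum(np.ceil((path.max(axis=0) + rmax) / spacing).astype(int) + 1, shape)
    if np.any(lo >= hi):
        return np.zeros(shape, dtype=bool)
    sub_coords = np.meshgrid(
        *[np.arange(l, h) * s for l, h, s in zip(lo, hi, spacing)], indexing="ij"
    )
    vox = np.stack([c.ravel() for c in sub_coords], axis=1)
    tree = spatial.cKDTree(path)
    dist, idx = tree.query(vox, k=1)
    # half a path step of slack keeps voxel centres lying exactly on the tube
    # surface inside despite the discrete path sampling
    step = td[1] - td[0] if len(td) > 1 else 0.0
    inside = dist <= radii[idx] + 0.5 * step
    mask = np.zeros(shape, dtype=bool)
    mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = inside.reshape(
        tuple(h - l for l, h in zip(lo, hi))
    )
    return mask


def generate_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Rasterize, blur and degrade one phantom; labels come from pure geometry.

    Raises when the core is not fully inside the nodule or when a vessel
    flagged ``crossing`` does not exit it.
    """
    shape, spacing = tuple(spec.shape), tuple(spec.spacing)
    nodule = _ellipsoid_mask(shape, spacing, spec.nodule_center, spec.nodule_radii)

    vessel_geom = np.zeros(shape, dtype=bool)
    vessel_rasters = []
    for v in spec.vessels:
        if v.crossing:
            ends_out = [
                not _inside_ellipsoid(p, spec.nodule_center, spec.nodule_radii)
                for p in (v.points[0], v.points[-1])
            ]
            if not all(ends_out):
                raise ValueError("a crossing vessel path must start and end outside the nodule")
        raster = _rasterize_vessel(v, shape, spacing)
        vessel_rasters.append(raster)
        vessel_geom |= raster

    core_geom = np.zeros(shape, dtype=bool)
    if spec.core is not None:
        c, r = spec.core.center, spec.core.radius
        for ax in range(3):
            for sgn in (-1, 1):
                p = list(c)
                p[ax] += sgn * r
                if not _inside_ellipsoid(p, spec.nodule_center, spec.nodule_radii):
                    raise ValueError(
                        f"core sphere (centre {c}, radius {r} mm) extends outside the nodule"
                    )
        core_geom = _ellipsoid_mask(shape, spacing, c, (r, r, r))

    # pre-blur image from geometry
    img = np.full(shape, spec.background_hu, dtype=np.float64)
    img[nodule] = spec.ggo_hu
    for v, raster in zip(spec.vessels, vessel_rasters):
        img[raster] = v.hu
    if spec.core is not None:
        img[core_geom] = spec.core.hu

    # truth on the pre-blur geometry; precedence core > vessel > ggo
    truth = np.zeros(shape, dtype=np.int16)
    truth[nodule] = GROUND_GLASS
    truth[vessel_geom & nodule] = VESSEL
    truth[core_geom & nodule] = CORE

    if spec.blur_sigma_mm > 0:
        img = ndimage.gaussian_filter(img, [spec.blur_sigma_mm / s for s in spacing])
    if spec.noise_sigma_hu > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma_hu, size=shape)

    return PhantomBundle(
        volume=Volume(img, spacing),
        nodule=LabelMap(nodule.astype(np.uint8), spacing),
        truth=LabelMap(truth, spacing),
        outer_vessels=LabelMap((vessel_geom & ~nodule).astype(np.uint8), spacing),
        spec=spec,
    )


#: The four strata of the balanced evaluation subset.
STRATA = (
    ("non-solid", False),
    ("non-solid+vessels", True),
    ("part-solid", False),
    ("part-solid+vessels", True),
)

DEFAULT_RANGES = {
    "nodule_radius_mm": (5.5, 8.0),
    "core_radius_fraction": (0.45, 0.6),
    "n_vessels": (1, 2),
    "vessel_diameter_mm": (2.2, 3.2),
    "vessel_taper": (0.85, 1.0),
}


def _random_unit_vector(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _chord_distance(d1, p1, d2, p2) -> float:
    """Distance between two infinite lines given unit directions and points."""
    n = np.cross(d1, d2)
    nn = np.linalg.norm(n)
    if nn < 1e-9:  # parallel
        return float(np.linalg.norm(np.cross(d1, p2 - p1)))
    return float(abs(np.dot(n / nn, p2 - p1)))


def _crossing_vessel(
    rng, spec_center, radii, shape, spacing, diameter, taper,
    avoid_spheres=(), avoid_vessels=(), clearance=0.5,
) -> VesselSpec:
    """A tube through the nodule along a random direction, spanning the grid.

    Directions and through-points are rejection-sampled so the tube keeps
    ``clearance`` mm away from the spheres in ``avoid_spheres`` (the solid
    core — a vessel piercing the core would make the two classes locally
    indistinguishable) and from previously placed vessels in
    ``avoid_vessels`` (crossing vessels are separate branches, not X-shaped
    intersections).  The best candidate is kept if no sample achieves the
    clearance.
    """
    best = None
    for _ in range(60):
        direction = _random_unit_vector(rng)
        through = np.asarray(spec_center) + rng.uniform(-0.3, 0.3, size=3) * np.asarray(radii)
        margin = np.inf
        for c, r in avoid_spheres:
            dist = np.linalg.norm(np.cross(direction, through - np.asarray(c)))
            margin = min(margin, dist - (r + diameter / 2.0))
        for od, op, orad in avoid_vessels:
            dist = _chord_distance(direction, through, np.asarray(od), np.asarray(op))
            margin = min(margin, dist - (orad + diameter / 2.0))
        if best is None or margin > best[0]:
            best = (margin, direction, through)
        if margin >= clearance:
            break
    _, direction, through = best
    extent = np.asarray(shape) * np.asarray(spacing)
    # scale to reach a margin inside the grid bounds in both directions
    ts = []
    for sgn in (-1.0, 1.0):
        t = np.inf
        for ax in range(3):
            d = direction[ax] * sgn
            if abs(d) > 1e-9:
                room = (extent[ax] - 2.0 - through[ax]) if d > 0 else (through[ax] - 2.0)
                t = min(t, room / abs(d))
        ts.append(max(t, 1.0))
    p0 = through - direction * ts[0]
    p1 = through + direction * ts[1]
    # gentle curvature: offset the midpoint perpendicular to the axis
    perp = np.cross(direction, _random_unit_vector(rng))
    norm = np.linalg.norm(perp)
    mid = (p0 + p1) / 2 + (perp / norm * rng.uniform(0.0, 0.8) if norm > 1e-6 else 0.0)
    spec = VesselSpec(
        points=[tuple(p0), tuple(mid), tuple(p1)],
        diameters=[diameter, diameter * (1 + taper) / 2, diameter * taper],
        crossing=True,
    )
    return spec, (direction, through, diameter / 2.0)


def sample_spec(rng, stratum: tuple, ranges=None, shape=DEFAULT_SHAPE, spacing=DEFAULT_SPACING,
                noise_sigma_hu: float = DEFAULT_NOISE_SIGMA_HU) -> PhantomSpec:
    """Draw one phantom spec for a given (type, has-vessels) stratum."""
    ranges = {**DEFAULT_RANGES, **(ranges or {})}
    name, has_vessels = stratum
    part_solid = name.startswith("part-solid")
    radii = tuple(rng.uniform(*ranges["nodule_radius_mm"], size=3))
    center = tuple(
        (n - 1) * s / 2.0 + rng.uniform(-1.0, 1.0) for n, s in zip(shape, spacing)
    )
    core = None
    if part_solid:
        frac = rng.uniform(*ranges["core_radius_fraction"])
        r_core = frac * min(radii)
        # eccentric core (common for part-solid nodules); leaves ground-glass
        # room for vessels on the far side
        offset = _random_unit_vector(rng) * (min(radii) - r_core) * rng.uniform(0.3, 0.6)
        core = CoreSpec(center=tuple(np.asarray(center) + offset), radius=r_core)
    vessels = []
    if has_vessels:
        n_vessels = int(rng.integers(ranges["n_vessels"][0], ranges["n_vessels"][1] + 1))
        avoid_spheres = [(core.center, core.radius)] if core is not None else []
        placed = []
        for _ in range(n_vessels):
            vspec, chord = _crossing_vessel(
                rng,
                center,
                radii,
                shape,
                spacing,
                diameter=rng.uniform(*ranges["vessel_diameter_mm"]),
                taper=rng.uniform(*ranges["vessel_taper"]),
                avoid_spheres=avoid_spheres,
                avoid_vessels=placed,
            )
            vessels.append(vspec)
            placed.append(chord)
    return PhantomSpec(
        shape=shape,
        spacing=spacing,
        nodule_center=center,
        nodule_radii=radii,
        core=core,
        vessels=vessels,
        noise_sigma_hu=noise_sigma_hu,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_cohort(
    n: int,
    seed: int = 0,
    ranges: dict | None = None,
    strata=STRATA,
    shape=DEFAULT_SHAPE,
    spacing=DEFAULT_SPACING,
    noise_sigma_hu: float = DEFAULT_NOISE_SIGMA_HU,
) -> tuple[list[PhantomBundle], list[dict]]:
    """Generate ``n`` phantoms cycling through the strata, plus a manifest.

    With ``n`` a multiple of the stratum count the cohort is balanced (e.g.
    n = 16 gives 4 phantoms per stratum).  The manifest records every sampled
    parameter; two runs with the same seed produce identical manifests and
    bit-identical phantoms.
    """
    if n < 1:
        raise ValueError("need at least one phantom")
    rng = np.random.default_rng(seed)
    bundles, manifest = [], []
    for i in range(n):
        stratum = strata[i % len(strata)]
        spec = sample_spec(rng, stratum, ranges, shape, spacing, noise_sigma_hu)
        bundle = generate_phantom(spec)
        bundles.append(bundle)
        manifest.append(
            {
                "phantom_id": i,
                "stratum": stratum[0],
                "has_vessels": stratum[1],
                "nodule_center_mm": list(spec.nodule_center),
                "nodule_radii_mm": list(spec.nodule_radii),
                "diameter_mm": 2.0 * float(np.mean(spec.nodule_radii)),
                "core_radius_mm": spec.core.radius if spec.core else None,
                "n_vessels": len(spec.vessels),
                "vessel_diameters_mm": [v.diameters[0] for v in spec.vessels],
                "noise_sigma_hu": spec.noise_sigma_hu,
                "complex": False,
                "seed": spec.seed,
            }
        )
    return bundles, manifest


def sparse_annotations(
    truth: LabelMap, per_class: int, seed: int = 0, manifest_warnings: list | None = None
) -> LabelMap:
    """Random sparse expert-style annotations drawn from the truth labels.

    Samples up to ``per_class`` voxels per class without replacement,
    stratified over the 26-connected components of each class so that every
    structure (each vessel, each core) contributes approximately equally —
    emulating an annotator marking vessels and cores of multiple sizes
    throughout the nodule.  Classes absent from the truth are skipped with a
    warning entry.
    """
    from .classify import _waterfill_quota  # shared quota arithmetic

    if per_class < 1:
        raise ValueError("per_class must be >= 1")
    rng = np.random.default_rng(seed)
    out = np.zeros(truth.shape, dtype=np.int16)
    struct = ndimage.generate_binary_structure(3, 3)
    for cls in (VESSEL, CORE, GROUND_GLASS):
        cls_mask = truth.data == cls
        if not cls_mask.any():
            if manifest_warnings is not None:
                manifest_warnings.append(f"class {cls} absent from truth; skipped")
            continue
        lab, ncomp = ndimage.label(cls_mask, structure=struct)
        avail = np.array([int(np.sum(lab == i + 1)) for i in range(ncomp)])
        quota = _waterfill_quota(avail, per_class)
        for i, q in enumerate(quota):
            pool = np.flatnonzero(lab.ravel() == i + 1)
            pick = rng.choice(pool, size=int(q), replace=False)
            out.ravel()[pick] = cls
    return LabelMap(out, truth.spacing, truth.origin)
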