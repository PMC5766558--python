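"""Vascular-continuity regularization of the initial vessel segmentation.

Vessels form a tree with smoothly tapering calibre, so a true vessel segment
inside a nodule must (a) attach to a vessel entering the nodule and (b) be no
wider than that entering vessel.  The analysis:

1. split the initial in-nodule vessel set into 6-connected components
   ``i_in``;
2. for each component, find its *entering vessel* ``i_out`` among the
   26-connected outside-vessel components: it must touch ``i_in``, be at
   least as large as any other attached outside vessel, and be connected to
   the vascular tree (the dominant outside component) — this last criterion
   keeps noise in the outside segmentation from anchoring continuity;
3. estimate a per-voxel diameter ``d_in(x)`` for the inside component and a
   mean diameter ``d_out`` for the entering vessel close to the nodule
   border (local-thickness via inscribed spheres on the Euclidean distance
   transform);
4. convert the ratio into a continuity weight::

       w_vc(x) = 1                                  if d_in(x) <= d_out
                 0                                  if d_in(x) >= a * d_out
                 1 - (d_in(x)/d_out - 1) / (a - 1)  otherwise

   with the cutoff ``a = 3`` by default;
5. re-run the weighted argmax with the vessel likelihood attenuated to
   ``L_v(x) = w_v * w_vc(x) * P_v(x)`` and re-apply solitary smoothing.

Components with no entering vessel are anatomically implausible and get
``w_vc = 0`` (configurable).  Voxels never labeled vessel keep ``w_vc = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import sato

from .classify import ClassWeights, PosteriorStack, argmax_labels, smooth_solitary
from .volume import VESSEL, LabelMap, Volume

DEFAULT_A = 3.0
DEFAULT_BORDER_BAND_MM = 2.0

_STRUCT6 = ndimage.generate_binary_structure(3, 1)
_STRUCT26 = ndimage.generate_binary_structure(3, 3)


@dataclass
class VesselComponent:
    """A 6-connected component of the initial in-nodule vessel set."""

    component_id: int
    voxels: np.ndarray  # (n, 3) integer indices
    entering_vessel_id: int | None = None
    d_out: float | None = None  # mean entering-vessel diameter (mm)

    def __post_init__(self) -> None:
        if len(self.voxels) == 0:
            raise ValueError("a vessel component must contain at least one voxel")
        if self.entering_vessel_id is not None and (self.d_out is None or self.d_out <= 0):
            raise ValueError("components with an entering vessel need d_out > 0")


@dataclass
class ContinuityField:
    """Per-voxel continuity weights over the initial vessel set."""

    w_vc: np.ndarray  # full-grid float map in [0, 1]
    d_in: np.ndarray  # full-grid diameter map (mm), 0 outside the vessel set
    a: float = DEFAULT_A
    components: list[VesselComponent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.a <= 1:
            raise ValueError(f"cutoff parameter a must be > 1, got {self.a}")
        if self.w_vc.min() < -1e-12 or self.w_vc.max() > 1 + 1e-12:
            raise ValueError("w_vc must lie in [0, 1]")


def continuity_weight(d_in, d_out: float, a: float = DEFAULT_A):
    """The piecewise-linear continuity weight for diameter ratio d_in/d_out.

    1 for ``d_in <= d_out``, 0 for ``d_in >= a * d_out``, linear in between;
    continuous at both breakpoints.  Accepts scalars or arrays of ``d_in``.
    """
    if d_out <= 0:
        raise ValueError(f"d_out must be > 0, got {d_out}")
    if a <= 1:
        raise ValueError(f"a must be > 1, got {a}")
    ratio = np.asarray(d_in, dtype=np.float64) / d_out
    w = 1.0 - (ratio - 1.0) / (a - 1.0)
    w = np.clip(w, 0.0, 1.0)
    w = np.where(ratio <= 1.0, 1.0, w)
    w = np.where(ratio >= a, 0.0, w)
    if np.isscalar(d_in):
        return float(w)
    return w


def split_components(vessel_mask: np.ndarray | LabelMap) -> tuple[np.ndarray, list[VesselComponent]]:
    """Partition a binary in-nodule vessel set into 6-connected components.

    Returns ``(label_array, components)``; component ids are 1-based and
    ordered by each component's minimal lexicographic voxel, so they are
    deterministic.
    """
    arr = vessel_mask.data > 0 if isinstance(vessel_mask, LabelMap) else np.asarray(vessel_mask) > 0
    lab, n = ndimage.label(arr, structure=_STRUCT6)
    if n == 0:
        return lab, []
    flat = lab.ravel()
    first = np.full(n + 1, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    # first (lexicographically smallest) voxel per raw label
    np.minimum.at(first, flat[nz], nz)
    order = np.argsort(first[1:], kind="stable")  # raw label -> rank
    remap = np.zeros(n + 1, dtype=lab.dtype)
    remap[1 + order] = np.arange(1, n + 1)
    lab = remap[lab]
    comps = [
        VesselComponent(component_id=i, voxels=np.argwhere(lab == i)) for i in range(1, n + 1)
    ]
    return lab, comps


def local_thickness(mask: np.ndarray, spacing) -> np.ndarray:
    """Per-voxel structure diameter (mm) by the inscribed-sphere definition.

    ``d(x) = 2 * max{ r(y) : |x - y| <= r(y) }`` where ``r`` is the Euclidean
    distance transform of the mask — i.e. the diameter of the largest sphere
    fully inside the structure that covers ``x``.  Spheres are painted in
    decreasing radius order; voxels already covered by a larger sphere are
    skipped.
    """
    mask = np.asarray(mask) > 0
    if not mask.any():
        raise ValueError("cannot estimate diameters of an empty mask")
    spacing = np.asarray(spacing, dtype=np.float64)
    edt = ndimage.distance_transform_edt(mask, sampling=spacing)
    out = np.zeros_like(edt)
    coords = np.argwhere(mask)
    radii = edt[mask]
    order = np.argsort(-radii, kind="stable")
    shape = np.array(mask.shape)
    for ci in order:
        z, y, x = coords[ci]
        r = radii[ci]
        if out[z, y, x] >= 2.0 * r:
            continue  # already covered by a larger sphere
        half = np.ceil(r / spacing).astype(int)
        lo = np.maximum([z, y, x] - half, 0)
        hi = np.minimum([z, y, x] + half + 1, shape)
        zz, yy, xx = np.meshgrid(
            (np.arange(lo[0], hi[0]) - z) * spacing[0],
            (np.arange(lo[1], hi[1]) - y) * spacing[1],
            (np.arange(lo[2], hi[2]) - x) * spacing[2],
            indexing="ij",
        )
        inside = zz * zz + yy * yy + xx * xx <= r * r
        box = out[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        np.maximum(box, np.where(inside, 2.0 * r, 0.0), out=box)
    return out


def estimate_diameters(
    vessel_voxels: np.ndarray, full_vessel_mask: np.ndarray, spacing
) -> np.ndarray:
    """Local-thickness diameters (mm) at the given voxels.

    The thickness field is computed over ``full_vessel_mask`` (typically the
    union of inside and outside vessel voxels, so calibre is not clipped at
    the nodule border) and sampled at ``vessel_voxels`` ((n, 3) indices).
    Strictly positive everywhere on the mask.
    """
    if abs(spacing[0] - spacing[1]) > 1e-9 or abs(spacing[1] - spacing[2]) > 1e-9:
        raise ValueError(f"diameter estimation expects an isotropic grid, got spacing {tuple(spacing)}")
    thick = local_thickness(full_vessel_mask, spacing)
    d = thick[tuple(np.asarray(vessel_voxels).T)]
    # a voxel is at least as thick as one inscribed voxel sphere
    return np.maximum(d, float(min(spacing)))


def outer_vessel_mask(
    vol: Volume,
    lung_or_roi: np.ndarray | LabelMap,
    nodule: np.ndarray | LabelMap,
    external_mask: np.ndarray | LabelMap | None = None,
    sigmas_mm: tuple[float, ...] = (0.75, 1.25, 2.0),
    tubularity_threshold: float = 60.0,
    hu_threshold: float = -600.0,
) -> LabelMap:
    """Binary segmentation of vessels outside the nodule.

    An externally supplied vessel mask (from any dedicated lung-vessel
    segmenter) bypasses the default and is returned restricted to
    ``roi & ~nodule``.  The default is a multi-scale Sato tubularity filter on
    the standardized HU volume, thresholded and combined with a soft-tissue HU
    guard — a simple stand-in adequate for high-contrast vessels.
    """
    roi = lung_or_roi.data > 0 if isinstance(lung_or_roi, LabelMap) else np.asarray(lung_or_roi) > 0
    nod = nodule.data > 0 if isinstance(nodule, LabelMap) else np.asarray(nodule) > 0
    if not roi.any():
        raise ValueError("empty ROI: nothing to segment vessels in")
    outside = roi & ~nod
    if external_mask is not None:
        ext = (
            external_mask.data > 0
            if isinstance(external_mask, LabelMap)
            else np.asarray(external_mask) > 0
        )
        return LabelMap((ext & outside).astype(np.uint8), vol.spacing, vol.origin)
    sp = vol.spacing[0]
    if not vol.is_isotropic:
        raise ValueError("default outer-vessel segmentation expects a standardized isotropic volume")
    data = vol.data.astype(np.float64)
    tub = np.zeros(vol.shape)
    for s in sigmas_mm:
        np.maximum(tub, sato(data, sigmas=[s / sp], black_ridges=False), out=tub)
    mask = (tub > tubularity_threshold) & (data > hu_threshold) & outside
    return LabelMap(mask.astype(np.uint8), vol.spacing, vol.origin)


def _nodule_border_band(nodule: np.ndarray, spacing, band_mm: float) -> np.ndarray:
    """Voxels outside the nodule within ``band_mm`` of its boundary."""
    dist = ndimage.distance_transform_edt(~nodule, sampling=spacing)
    return (~nodule) & (dist <= band_mm)


def find_entering_vessels(
    components: list[VesselComponent],
    inner_label_array: np.ndarray,
    outer_mask: np.ndarray,
    nodule: np.ndarray,
    spacing,
    border_band_mm: float = DEFAULT_BORDER_BAND_MM,
    thickness: np.ndarray | None = None,
    tree_min_fraction: float = 0.1,
) -> list[VesselComponent]:
    """Attach each inside component to its entering vessel, when one exists.

    Outside vessels are 26-connected components of ``outer_mask``; the
    vascular tree is the set of components whose voxel count is at least
    ``tree_min_fraction`` of the largest one — this keeps small segmentation
    noise from anchoring continuity while admitting several major vessels.  A
    candidate entering vessel must be 26-adjacent to the inside component and
    belong to the tree; among candidates the one with the largest mean
    diameter near the nodule border wins (ties: larger voxel count, then
    smaller id).  ``d_out`` is that mean diameter.  Components with no
    qualifying outside vessel keep ``entering_vessel_id = None``.
    """
    outer_lab, n_outer = ndimage.label(np.asarray(outer_mask) > 0, structure=_STRUCT26)
    if n_outer == 0:
        return components
    sizes = np.bincount(outer_lab.ravel())[1:]
    tree_ids = {int(i + 1) for i in range(n_outer) if sizes[i] >= tree_min_fraction * sizes.max()}
    union = (np.asarray(outer_mask) > 0) | (inner_label_array > 0)
    if thickness is None:
        thickness = local_thickness(union, spacing)
    edt = ndimage.distance_transform_edt(union, sampling=spacing)
    band = _nodule_border_band(np.asarray(nodule) > 0, spacing, border_band_mm)

    for comp in components:
        comp_mask = inner_label_array == comp.component_id
        touch = ndimage.binary_dilation(comp_mask, structure=_STRUCT26)
        cand_ids = np.unique(outer_lab[touch & (outer_lab > 0)])
        cand_ids = [int(i) for i in cand_ids if int(i) in tree_ids]
        best = None
        for oid in cand_ids:
            ovox = outer_lab == oid
            near = ovox & band
            sel = near if near.any() else ovox
            # average calibre over the *central* voxels (upper half of the
            # distance transform): the surface shell of a digital tube would
            # otherwise bias the estimate low
            central = sel & (edt >= 0.5 * edt[sel].max())
            d_out = float(thickness[central if central.any() else sel].mean())
            key = (d_out, int(ovox.sum()), -oid)
            if best is None or key > best[0]:
                best = (key, oid, d_out)
        if best is not None:
            comp.entering_vessel_id = best[1]
            comp.d_out = best[2]
    return components


def compute_continuity_field(
    initial_labels: LabelMap,
    nodule: np.ndarray | LabelMap,
    outer_mask: np.ndarray | LabelMap,
    a: float = DEFAULT_A,
    border_band_mm: float = DEFAULT_BORDER_BAND_MM,
    unattached_weight: float = 0.0,
) -> ContinuityField:
    """Full continuity analysis for an initial segmentation.

    Returns a field with ``w_vc = 1`` on voxels never labeled vessel, the
    Eq.-style piecewise weight on attached components, and
    ``unattached_weight`` (default 0: anatomically implausible) on components
    without an entering vessel.
    """
    nod = nodule.data > 0 if isinstance(nodule, LabelMap) else np.asarray(nodule) > 0
    outer = outer_mask.data > 0 if isinstance(outer_mask, LabelMap) else np.asarray(outer_mask) > 0
    inner = (initial_labels.data == VESSEL) & nod
    spacing = initial_labels.spacing

    w_vc = np.ones(initial_labels.shape)
    d_in_map = np.zeros(initial_labels.shape)
    lab, comps = split_components(inner)
    if not comps:
        return ContinuityField(w_vc=w_vc, d_in=d_in_map, a=a, components=[])

    union = inner | outer
    thickness = local_thickness(union, spacing)
    comps = find_entering_vessels(
        comps, lab, outer, nod, spacing, border_band_mm, thickness=thickness
    )
    for comp in comps:
        vz = tuple(comp.voxels.T)
        d_in = np.maximum(thickness[vz], float(min(spacing)))
        d_in_map[vz] = d_in
        if comp.entering_vessel_id is None:
            w_vc[vz] = unattached_weight
        else:
            w_vc[vz] = continuity_weight(d_in, comp.d_out, a)
    return ContinuityField(w_vc=w_vc, d_in=d_in_map, a=a, components=comps)


def apply_continuity(
    post: PosteriorStack,
    weights: ClassWeights,
    field: ContinuityField,
    mask: np.ndarray | LabelMap | None = None,
    smooth: bool = True,
) -> LabelMap:
    """Final segmentation with the vessel likelihood attenuated by ``w_vc``.

    Recomputes the weighted argmax with ``L_v = w_v * w_vc * P_v`` (core and
    ground-glass likelihoods unchanged) and re-applies solitary smoothing.
    Because only the vessel likelihood is attenuated, the final vessel set
    (pre-smoothing) is a subset of the initial one.
    """
    if field.w_vc.shape != post.mask.shape:
        raise ValueError(
            f"continuity field shape {field.w_vc.shape} does not match posteriors {post.mask.shape}"
        )
    if mask is None:
        mask_arr = post.mask
    else:
        mask_arr = mask.data > 0 if isinstance(mask, LabelMap) else np.asarray(mask) > 0
    L = post.p * weights.as_array()[:, None, None, None]
    L[VESSEL - 1] *= field.w_vc
    flat = L.reshape(3, -1).T[mask_arr.ravel()]
    labels = np.zeros(post.mask.shape, dtype=np.int16)
    labels.ravel()[mask_arr.ravel()] = argmax_labels(flat)
    out = LabelMap(labels, post.spacing, post.origin)
    if smooth:
        out = smooth_solitary(out, mask_arr, L)
    return out
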