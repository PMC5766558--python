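"""Per-voxel descriptors for the three-class voxel classifier.

Each voxel inside the nodule is described by a 17-dimensional vector that
separates tubular soft tissue (vessels) from blob-like soft tissue (solid
cores) and from ground-glass attenuation:

* multi-scale second-order shape: Hessian eigenvalues ``l1, l2, l3`` sorted by
  decreasing magnitude (``|l1| >= |l2| >= |l3|``) and the gradient magnitude,
  at Gaussian scales sigma = 1, 2, 4 mm  -> 12 columns.
  A bright tube has one small and two large-negative eigenvalues; a bright
  blob has three similar negative eigenvalues.
* intensity: raw HU (1), Gaussian-smoothed HU at the same three scales (3),
  and the standard deviation over the 26-neighbourhood incl. the centre
  voxel (1)  -> 5 columns.

All derivatives are Gaussian derivatives at physical scale (mm) on an
isotropic grid; anisotropic input is rejected with a pointer to
:func:`subsolidseg.standardize.resample_isotropic`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import LabelMap, Volume

DEFAULT_SCALES = (1.0, 2.0, 4.0)  # mm
GAUSSIAN_TRUNCATE = 4.0  # derivative kernels truncated at 4 sigma


@dataclass
class FeatureSpec:
    """Which feature blocks to compute and at which scales."""

    scales: tuple[float, ...] = DEFAULT_SCALES
    include_eigenvalues: bool = True
    include_gradient: bool = True
    include_smoothed_hu: bool = True
    include_raw_hu: bool = True
    include_neighborhood_std: bool = True
    #: whether the 26-neighbourhood std includes the centre voxel (27 values)
    std_includes_center: bool = True

    def __post_init__(self) -> None:
        self.scales = tuple(float(s) for s in self.scales)
        if any(s <= 0 for s in self.scales):
            raise ValueError(f"scales must be strictly positive, got {self.scales}")
        if not any(
            [
                self.include_eigenvalues,
                self.include_gradient,
                self.include_smoothed_hu,
                self.include_raw_hu,
                self.include_neighborhood_std,
            ]
        ):
            raise ValueError("at least one feature block must be enabled")

    def feature_names(self) -> list[str]:
        names: list[str] = []
        for s in self.scales:
            tag = f"s{s:g}"
            if self.include_eigenvalues:
                names += [f"l1_{tag}", f"l2_{tag}", f"l3_{tag}"]
            if self.include_gradient:
                names.append(f"grad_{tag}")
        if self.include_raw_hu:
            names.append("hu")
        if self.include_smoothed_hu:
            names += [f"hu_s{s:g}" for s in self.scales]
        if self.include_neighborhood_std:
            names.append("nstd26")
        return names

    def to_dict(self) -> dict:
        return {
            "scales": list(self.scales),
            "include_eigenvalues": self.include_eigenvalues,
            "include_gradient": self.include_gradient,
            "include_smoothed_hu": self.include_smoothed_hu,
            "include_raw_hu": self.include_raw_hu,
            "include_neighborhood_std": self.include_neighborhood_std,
            "std_includes_center": self.std_includes_center,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSpec":
        d = dict(d)
        d["scales"] = tuple(d["scales"])
        return cls(**d)


@dataclass
class FeatureMatrix:
    """Rows of per-voxel features, in lexicographic voxel order."""

    values: np.ndarray  # (n_samples, n_features)
    feature_names: list[str]
    voxel_index: np.ndarray  # linear index into the source grid
    grid_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must equal the column count")
        bad = ~np.isfinite(self.values)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"non-finite feature '{self.feature_names[c]}' at voxel "
                f"{np.unravel_index(self.voxel_index[r], self.grid_shape)}"
            )


def _require_isotropic(vol: Volume) -> float:
    if not vol.is_isotropic:
        raise ValueError(
            f"features require an isotropic grid, got spacing {vol.spacing}; "
            "resample with standardize.resample_isotropic first"
        )
    return vol.spacing[0]


def hessian_eigenvalues(vol: Volume, sigma: float):
    """Hessian eigenvalue maps at physical scale ``sigma`` (mm).

    Returns three maps ``(l1, l2, l3)`` with ``|l1| >= |l2| >= |l3|`` at every
    voxel; signs are retained (bright structures on a dark background give
    negative leading eigenvalues).
    """
    sp = _require_isotropic(vol)
    sv = sigma / sp
    # remove the DC offset: the sampled second-derivative kernels do not sum
    # exactly to zero, so a constant would otherwise leak into the Hessian
    data = vol.data.astype(np.float64)
    data = data - data.mean()
    H = np.empty(vol.shape + (3, 3))
    for i in range(3):
        for j in range(i, 3):
            order = [0, 0, 0]
            order[i] += 1
            order[j] += 1
            d2 = ndimage.gaussian_filter(data, sv, order=order, truncate=GAUSSIAN_TRUNCATE)
            d2 /= sp * sp  # index derivatives -> HU / mm^2
            H[..., i, j] = d2
            H[..., j, i] = d2
    eig = np.linalg.eigvalsh(H.reshape(-1, 3, 3))
    order = np.argsort(-np.abs(eig), axis=1, kind="stable")
    eig = np.take_along_axis(eig, order, axis=1).reshape(vol.shape + (3,))
    return eig[..., 0], eig[..., 1], eig[..., 2]


def gradient_magnitude(vol: Volume, sigma: float) -> np.ndarray:
    """Euclidean norm of the Gaussian first-derivative vector (HU/mm)."""
    sp = _require_isotropic(vol)
    sv = sigma / sp
    data = vol.data.astype(np.float64)
    sq = np.zeros(vol.shape)
    for ax in range(3):
        order = [0, 0, 0]
        order[ax] = 1
        d = ndimage.gaussian_filter(data, sv, order=order, truncate=GAUSSIAN_TRUNCATE) / sp
        sq += d * d
    return np.sqrt(sq)


def neighborhood_std(vol: Volume, include_center: bool = True) -> np.ndarray:
    """Population standard deviation over the 26-neighbourhood of each voxel.

    Interior voxels pool 27 values (centre included by default); edge voxels
    use only the neighbours that exist.
    """
    data = vol.data.astype(np.float64)
    kernel = np.ones((3, 3, 3))
    if not include_center:
        kernel[1, 1, 1] = 0.0
    count = ndimage.correlate(np.ones_like(data), kernel, mode="constant", cval=0.0)
    s1 = ndimage.correlate(data, kernel, mode="constant", cval=0.0)
    s2 = ndimage.correlate(data * data, kernel, mode="constant", cval=0.0)
    mean = s1 / count
    var = np.maximum(s2 / count - mean * mean, 0.0)
    return np.sqrt(var)


def smoothed_hu(vol: Volume, sigma: float) -> np.ndarray:
    """Gaussian-smoothed HU at physical scale sigma (mm)."""
    sp = _require_isotropic(vol)
    return ndimage.gaussian_filter(
        vol.data.astype(np.float64), sigma / sp, truncate=GAUSSIAN_TRUNCATE
    )


def assemble_features(
    vol: Volume, mask: LabelMap | np.ndarray, spec: FeatureSpec | None = None
) -> FeatureMatrix:
    """Build the per-voxel feature matrix over a mask.

    Rows are ordered by lexicographic (C-order) voxel index, so two calls on
    the same inputs produce bit-identical matrices.  With the default spec the
    matrix has 17 columns: 3 scales x (l1, l2, l3, |grad|) = 12, raw HU,
    smoothed HU x 3, 26-neighbourhood std.
    """
    spec = spec or FeatureSpec()
    mask_arr = mask.data > 0 if isinstance(mask, LabelMap) else np.asarray(mask) > 0
    if mask_arr.shape != vol.shape:
        raise ValueError(f"mask shape {mask_arr.shape} does not match volume {vol.shape}")
    idx = np.flatnonzero(mask_arr)
    if idx.size == 0:
        raise ValueError("empty mask: no voxels to featurize")
    flat = mask_arr.ravel()

    columns: list[np.ndarray] = []
    for s in spec.scales:
        if spec.include_eigenvalues:
            l1, l2, l3 = hessian_eigenvalues(vol, s)
            columns += [l1.ravel()[flat], l2.ravel()[flat], l3.ravel()[flat]]
        if spec.include_gradient:
            columns.append(gradient_magnitude(vol, s).ravel()[flat])
    if spec.include_raw_hu:
        columns.append(vol.data.astype(np.float64).ravel()[flat])
    if spec.include_smoothed_hu:
        for s in spec.scales:
            columns.append(smoothed_hu(vol, s).ravel()[flat])
    if spec.include_neighborhood_std:
        columns.append(neighborhood_std(vol, spec.std_includes_center).ravel()[flat])

    values = np.column_stack(columns)
    return FeatureMatrix(
        values=values,
        feature_names=spec.feature_names(),
        voxel_index=idx,
        grid_shape=vol.shape,
    )
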