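"""Image standardization: isotropic resampling and reconstruction-kernel normalization.

CT scans arrive at heterogeneous resolutions and reconstruction kernels.  The
classifier is trained on a fixed appearance, so every input is first resampled
to an isotropic grid (0.5 mm by default, trilinear interpolation) and then
passed through a frequency-band energy normalization that shifts the image
towards a soft reference kernel: the volume is decomposed into
difference-of-Gaussian bands, each band is rescaled by a gain estimated from
reference populations, and the bands are recombined.

Grids are node-aligned (see :mod:`subsolidseg.volume`); the output shape of a
resampling is ``round(extent / target)`` per axis, recorded in ``meta``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import LabelMap, Volume

DEFAULT_TARGET_SPACING = 0.5  # mm
#: Default band boundaries (mm) for kernel normalization; spans the feature scales.
DEFAULT_BAND_SIGMAS = (0.5, 1.0, 2.0, 4.0)


@dataclass
class KernelBandProfile:
    """Gains of a difference-of-Gaussians band decomposition.

    ``band_sigmas`` are the (strictly increasing) Gaussian scales in mm that
    bound the bands: band *b* is ``G[sigma_{b-1}] - G[sigma_b]`` with
    ``sigma_0 = 0`` (the identity).  ``gain_per_band`` multiplies each band;
    ``residual_gain`` multiplies the final low-pass ``G[sigma_last]``.
    With all gains at 1 the recombination is the identity.
    """

    band_sigmas: tuple[float, ...] = DEFAULT_BAND_SIGMAS
    gain_per_band: tuple[float, ...] | None = None
    residual_gain: float = 1.0

    def __post_init__(self) -> None:
        self.band_sigmas = tuple(float(s) for s in self.band_sigmas)
        if len(self.band_sigmas) == 0:
            raise ValueError("band_sigmas must be non-empty")
        if any(s <= 0 for s in self.band_sigmas):
            raise ValueError("band_sigmas must be strictly positive")
        if any(b <= a for a, b in zip(self.band_sigmas, self.band_sigmas[1:])):
            raise ValueError(f"band_sigmas must be strictly increasing, got {self.band_sigmas}")
        if self.gain_per_band is None:
            self.gain_per_band = tuple(1.0 for _ in self.band_sigmas)
        self.gain_per_band = tuple(float(g) for g in self.gain_per_band)
        if len(self.gain_per_band) != len(self.band_sigmas):
            raise ValueError("gain_per_band must have one gain per band sigma")
        gains = (*self.gain_per_band, self.residual_gain)
        if any((not np.isfinite(g)) or g <= 0 for g in gains):
            raise ValueError(f"all gains must be finite and > 0, got {gains}")

    def to_dict(self) -> dict:
        return {
            "band_sigmas": list(self.band_sigmas),
            "gain_per_band": list(self.gain_per_band),
            "residual_gain": self.residual_gain,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KernelBandProfile":
        return cls(
            band_sigmas=tuple(d["band_sigmas"]),
            gain_per_band=tuple(d["gain_per_band"]),
            residual_gain=float(d["residual_gain"]),
        )


def _output_shape(shape, spacing, target: float) -> tuple[int, ...]:
    return tuple(max(1, int(round(n * s / target))) for n, s in zip(shape, spacing))


def _resample(data: np.ndarray, spacing, target: float, order: int) -> np.ndarray:
    out_shape = _output_shape(data.shape, spacing, target)
    coords = np.meshgrid(
        *[np.arange(n) * target / s for n, s in zip(out_shape, spacing)],
        indexing="ij",
    )
    return ndimage.map_coordinates(
        data.astype(np.float64 if order > 0 else data.dtype),
        coords,
        order=order,
        mode="nearest",  # edge clamping outside the grid
    )


def resample_isotropic(vol: Volume, target_spacing: float = DEFAULT_TARGET_SPACING) -> Volume:
    """Resample a volume to an isotropic grid by trilinear interpolation.

    Output voxel ``j`` sits at physical position ``j * target_spacing`` along
    each axis (origin preserved); output shape is ``round(extent / target)``
    per axis, so the physical extent is preserved to within one voxel.
    """
    if target_spacing <= 0:
        raise ValueError(f"target_spacing must be > 0, got {target_spacing}")
    for ax, n in enumerate(vol.shape):
        if n < 2:
            raise ValueError(
                f"cannot resample along degenerate axis {ax} (size {n}); need >= 2 samples"
            )
    if vol.is_isotropic and abs(vol.spacing[0] - target_spacing) < 1e-12:
        return vol.with_data(vol.data.copy(), resample_rule="identity")
    out = _resample(vol.data, vol.spacing, target_spacing, order=1)
    return Volume(
        data=out,
        spacing=(target_spacing,) * 3,
        origin=vol.origin,
        meta={
            **vol.meta,
            "resample_rule": "node-aligned round(extent/target), edge clamp",
            "source_spacing": vol.spacing,
            "source_shape": vol.shape,
        },
    )


def resample_labels(labels: LabelMap, reference: Volume) -> LabelMap:
    """Resample a label map onto a reference grid by nearest neighbour.

    The label set is preserved (no interpolation between labels).  Requires a
    common origin; use it to carry masks along with a resampled image.
    """
    if any(abs(a - b) > 1e-6 for a, b in zip(labels.origin, reference.origin)):
        raise ValueError(
            f"label grid origin {labels.origin} does not match reference {reference.origin}; "
            "resampling across shifted origins is not supported"
        )
    if labels.shape == reference.shape and all(
        abs(a - b) < 1e-9 for a, b in zip(labels.spacing, reference.spacing)
    ):
        return LabelMap(labels.data.copy(), reference.spacing, reference.origin, labels.legend)
    coords = np.meshgrid(
        *[
            np.arange(n) * rs / ls
            for n, rs, ls in zip(reference.shape, reference.spacing, labels.spacing)
        ],
        indexing="ij",
    )
    out = ndimage.map_coordinates(labels.data, coords, order=0, mode="nearest")
    return LabelMap(out, reference.spacing, reference.origin, labels.legend)


def decompose_bands(
    vol: Volume, band_sigmas=DEFAULT_BAND_SIGMAS
) -> tuple[list[np.ndarray], np.ndarray]:
    """Split a volume into DoG bands plus the coarsest low-pass residual.

    Returns ``(bands, residual)`` with ``sum(bands) + residual == data`` exactly
    (up to floating point), since each band is the difference of consecutive
    low-pass images.
    """
    if not vol.is_isotropic:
        raise ValueError("kernel normalization expects an isotropic volume; resample first")
    if len(band_sigmas) == 0:
        raise ValueError("band_sigmas must be non-empty")
    data = vol.data.astype(np.float64)
    sp = vol.spacing[0]
    lowpass = [data]
    for s in band_sigmas:
        lowpass.append(ndimage.gaussian_filter(data, s / sp, truncate=4.0))
    bands = [lowpass[i] - lowpass[i + 1] for i in range(len(band_sigmas))]
    return bands, lowpass[-1]


def band_energy(band: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Sum of squared band values, optionally restricted to a body/lung mask."""
    if mask is not None:
        band = band[mask]
    return float(np.sum(band.astype(np.float64) ** 2))


def kernel_normalize(vol: Volume, profile: KernelBandProfile) -> Volume:
    """Rescale the frequency-band energies of a volume by a gain profile.

    ``output = residual_gain * lowpass + sum_b gain_b * band_b``.  An identity
    profile (all gains 1) reproduces the input exactly.
    """
    bands, residual = decompose_bands(vol, profile.band_sigmas)
    out = profile.residual_gain * residual
    for gain, band in zip(profile.gain_per_band, bands):
        out += gain * band
    return vol.with_data(out, kernel_profile=profile.to_dict())


def estimate_band_profile(
    sharp_vols: list[Volume],
    soft_vols: list[Volume],
    band_sigmas=DEFAULT_BAND_SIGMAS,
    masks_sharp: list[np.ndarray] | None = None,
    masks_soft: list[np.ndarray] | None = None,
) -> KernelBandProfile:
    """Estimate the band gains that map sharp-kernel scans to soft-kernel energy.

    Gains start from ``sqrt(mean soft energy / mean sharp energy)`` per band
    and are then refined by a small fixed-point iteration so that *applying*
    the profile to the sharp group reproduces the soft group's band energies
    — the adjacent difference-of-Gaussian bands overlap, so the plain energy
    ratio alone would absorb cross-band leakage into the gains.  The residual
    gain is left at 1 (the residual is dominated by the DC offset, whose
    ratio carries no kernel information).
    """
    if len(sharp_vols) == 0 or len(soft_vols) == 0:
        raise ValueError("need at least one volume per group")

    def group_energy(vols, masks):
        energies = np.zeros(len(band_sigmas))
        for i, v in enumerate(vols):
            bands, _ = decompose_bands(v, band_sigmas)
            m = None if masks is None else masks[i]
            energies += [band_energy(b, m) for b in bands]
        return energies / len(vols)

    e_sharp = group_energy(sharp_vols, masks_sharp)
    e_soft = group_energy(soft_vols, masks_soft)
    for b, e in enumerate(e_sharp):
        if e <= 0:
            raise ValueError(
                f"band {b} (sigma <= {band_sigmas[b]} mm) has zero energy in the sharp group; "
                "cannot form a gain"
            )
    gains = np.sqrt(e_soft / e_sharp)
    for _ in range(30):
        profile = KernelBandProfile(band_sigmas=tuple(band_sigmas), gain_per_band=tuple(gains))
        e_cur = group_energy(
            [kernel_normalize(v, profile) for v in sharp_vols], masks_sharp
        )
        step = np.sqrt(e_soft / np.maximum(e_cur, 1e-300))
        gains = gains * step
        if np.max(np.abs(step - 1.0)) < 1e-4:
            break
    return KernelBandProfile(band_sigmas=tuple(band_sigmas), gain_per_band=tuple(gains))


def identity_profile(band_sigmas=DEFAULT_BAND_SIGMAS) -> KernelBandProfile:
    """Profile with all gains 1 (no-op normalization)."""
    return KernelBandProfile(band_sigmas=tuple(band_sigmas))
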