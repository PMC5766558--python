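"""End-to-end pipeline: configuration, training harness, and segmentation runs.

``run_pipeline`` executes standardize -> features -> posteriors -> weighted
argmax -> vascular continuity -> final labels for one scan + nodule mask.
Label logic (weighted argmax, solitary smoothing, continuity) runs on the
standardized isotropic grid, where diameter estimation is well defined; the
posteriors and final labels are then transferred back to the source grid
(trilinear + renormalization for probabilities, nearest neighbour for
labels).

``train_on_bundles`` is the matching training harness over annotated volumes
(e.g. phantom bundles with sparse annotations): it standardizes every scan,
assembles features at the annotated voxels, balances the classes, optimizes
the class-weight operating point by grouped cross-validation, and fits the
kNN model.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml
from scipy import ndimage

from . import classify, continuity, standardize
from .features import FeatureSpec, assemble_features
from .phantom import PhantomBundle, sparse_annotations
from .volume import LabelMap, Volume


@dataclass
class PipelineConfig:
    """Every convention and tunable of the pipeline, serializable to YAML."""

    target_spacing: float = standardize.DEFAULT_TARGET_SPACING  # mm
    band_sigmas: tuple = standardize.DEFAULT_BAND_SIGMAS  # mm
    feature_scales: tuple = (1.0, 2.0, 4.0)  # mm
    std_includes_center: bool = True
    k: int = classify.DEFAULT_K
    grid_step: float = classify.DEFAULT_GRID_STEP
    #: damping of large-class dominance in the operating-point search
    class_balance_exponent: float = 0.3
    a: float = continuity.DEFAULT_A
    border_band_mm: float = continuity.DEFAULT_BORDER_BAND_MM
    unattached_weight: float = 0.0
    detection_connectivity: int = 26
    continuity_connectivity: int = 6
    sd_convention: str = "sample (ddof=1)"
    argmax_tie_break: str = "ground-glass > vessel > core"
    seed: int = 0

    def feature_spec(self) -> FeatureSpec:
        return FeatureSpec(scales=tuple(self.feature_scales), std_includes_center=self.std_includes_center)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self._plain_dict(), f, sort_keys=True)

    def _plain_dict(self) -> dict:
        d = asdict(self)
        d["band_sigmas"] = list(self.band_sigmas)
        d["feature_scales"] = list(self.feature_scales)
        return d

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as f:
            d = yaml.safe_load(f)
        d["band_sigmas"] = tuple(d["band_sigmas"])
        d["feature_scales"] = tuple(d["feature_scales"])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self._plain_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Everything a segmentation run produces, plus provenance."""

    final_labels: LabelMap  # on the source grid
    final_labels_std: LabelMap  # on the standardized grid
    initial_labels_std: LabelMap
    posteriors: classify.PosteriorStack  # on the source grid
    w_vc: np.ndarray  # standardized grid
    provenance: dict


def standardize_scan(
    scan: Volume, config: PipelineConfig, profile: standardize.KernelBandProfile | None = None
) -> Volume:
    vol_std = standardize.resample_isotropic(scan, config.target_spacing)
    if profile is not None:
        vol_std = standardize.kernel_normalize(vol_std, profile)
    return vol_std


def run_pipeline(
    scan: Volume,
    nodule_mask: LabelMap,
    model: classify.TrainedModel,
    vessel_mask: LabelMap | None = None,
    config: PipelineConfig | None = None,
    lung_roi: LabelMap | None = None,
    skip_continuity: bool = False,
) -> PipelineResult:
    """Segment vessels / solid core / ground-glass inside one nodule.

    ``vessel_mask`` (source grid, binary) plugs in an external outside-vessel
    segmentation; without it the default tubularity segmenter runs on the
    standardized scan within ``lung_roi`` (whole grid when omitted).
    Deterministic given the inputs, the model and the config.
    """
    config = config or PipelineConfig()
    stage = "standardize"
    try:
        vol_std = standardize_scan(scan, config, model.band_profile)
        mask_std = standardize.resample_labels(nodule_mask, vol_std)

        stage = "posteriors"
        post_std = classify.predict_posteriors(model, vol_std, mask_std)

        stage = "initial segmentation"
        initial = classify.initial_segmentation(post_std, model.weights, mask_std)

        stage = "vascular continuity"
        if skip_continuity:
            final_std = initial
            w_vc = np.ones(vol_std.shape)
        else:
            roi = (
                standardize.resample_labels(lung_roi, vol_std).data > 0
                if lung_roi is not None
                else np.ones(vol_std.shape, dtype=bool)
            )
            ext = (
                standardize.resample_labels(vessel_mask, vol_std)
                if vessel_mask is not None
                else None
            )
            outer = continuity.outer_vessel_mask(
                vol_std, roi, mask_std, external_mask=ext
            )
            cfield = continuity.compute_continuity_field(
                initial,
                mask_std,
                outer,
                a=config.a,
                border_band_mm=config.border_band_mm,
                unattached_weight=config.unattached_weight,
            )
            final_std = continuity.apply_continuity(post_std, model.weights, cfield, mask_std)
            w_vc = cfield.w_vc

        stage = "source-grid transfer"
        post_src = classify.predict_posteriors(model, vol_std, mask_std, source_grid=scan)
        if same_source := (
            scan.shape == vol_std.shape
            and all(abs(a - b) < 1e-9 for a, b in zip(scan.spacing, vol_std.spacing))
        ):
            final_src = final_std
        else:
            # re-run the weighted argmax on the back-interpolated posteriors,
            # with the continuity weights carried over by nearest neighbour
            coords = np.meshgrid(
                *[
                    np.arange(n) * ss / ts
                    for n, ss, ts in zip(scan.shape, scan.spacing, vol_std.spacing)
                ],
                indexing="ij",
            )
            w_vc_src = ndimage.map_coordinates(w_vc, coords, order=0, mode="nearest")
            field_src = continuity.ContinuityField(
                w_vc=w_vc_src, d_in=np.zeros_like(w_vc_src), a=config.a
            )
            final_src = continuity.apply_continuity(
                post_src, model.weights, field_src, nodule_mask.data > 0
            )
        # restrict to the original nodule mask on the source grid
        fs = final_src.data.copy()
        fs[nodule_mask.data == 0] = 0
        final_src = final_src.with_data(fs)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    provenance = {
        "config_hash": config.config_hash(),
        "config": config._plain_dict(),
        "model_version": model.format_version,
        "model_k": model.k,
        "weights": list(model.weights.as_array()),
        "skip_continuity": skip_continuity,
        "external_vessel_mask": vessel_mask is not None,
    }
    return PipelineResult(
        final_labels=final_src,
        final_labels_std=final_std,
        initial_labels_std=initial,
        posteriors=post_src,
        w_vc=w_vc,
        provenance=provenance,
    )


def train_on_bundles(
    bundles: list[PhantomBundle],
    per_class: int = 133,
    config: PipelineConfig | None = None,
    optimize: bool = True,
    seed: int = 0,
) -> classify.TrainedModel:
    """Train a model from phantom bundles with sparse truth annotations.

    Each bundle plays the role of one annotated patient nodule: its scan is
    standardized, ``per_class`` voxels per class are annotated from the truth,
    and features are assembled on the standardized grid.  Classes are
    balanced across nodules and the kNN is fit on the balanced samples
    (k clipped to the sample count when needed).

    The class-weight operating point is grid-searched on out-of-fold
    posteriors from leave-one-nodule-out folds, scored against the *full*
    reference segmentation of the held-out nodule — the total voxel-level
    hard-label disagreement the weights exist to minimize.  (Sparse
    annotations oversample thin classes relative to their voxel share, which
    would bias the operating point towards over-calling them.)
    """
    config = config or PipelineConfig()
    spec = config.feature_spec()
    full_fms, full_refs = [], []
    ann_values, ann_labels, ann_groups = [], [], []
    for gi, b in enumerate(bundles):
        vol_std = standardize_scan(b.volume, config)
        truth_std = standardize.resample_labels(b.truth, vol_std)
        fm = assemble_features(vol_std, truth_std.data > 0, spec)
        full_fms.append(fm)
        full_refs.append(truth_std.data.ravel()[fm.voxel_index].astype(int))
        ann = sparse_annotations(truth_std, per_class, seed=seed + 1000 * gi)
        rows = np.isin(fm.voxel_index, np.flatnonzero(ann.data.ravel() > 0))
        ann_values.append(fm.values[rows])
        ann_labels.append(ann.data.ravel()[fm.voxel_index[rows]])
        ann_groups.append(np.full(int(rows.sum()), gi))
    values = np.concatenate(ann_values)
    labels = np.concatenate(ann_labels).astype(int)
    groups = np.concatenate(ann_groups)

    values, labels, idx = classify.balance_classes(values, labels, groups, seed=seed)
    groups = groups[idx]
    k = classify.clipped_k(config.k, len(labels) - 1)
    if optimize and len(bundles) >= 2:
        fold_posteriors, fold_refs = [], []
        for gi in range(len(bundles)):
            train_rows = groups != gi
            fold_model = classify.train(
                values[train_rows],
                labels[train_rows],
                k=classify.clipped_k(k, int(train_rows.sum())),
                feature_spec=spec,
            )
            fold_posteriors.append(fold_model.predict_proba(full_fms[gi].values))
            fold_refs.append(full_refs[gi])
        weights = classify.optimize_weights_from_posteriors(
            np.vstack(fold_posteriors),
            np.concatenate(fold_refs),
            config.grid_step,
            class_balance_exponent=config.class_balance_exponent,
        )
    else:
        weights = classify.UNIFORM_WEIGHTS
    model = classify.train(values, labels, k=k, feature_spec=spec)
    model.weights = weights
    return model


def segment_bundle(
    bundle: PhantomBundle,
    model: classify.TrainedModel,
    config: PipelineConfig | None = None,
    use_true_outer_vessels: bool = True,
    skip_continuity: bool = False,
) -> PipelineResult:
    """Run the full pipeline on a phantom, by default with its known outside
    vessels plugged in as the external vessel segmentation."""
    return run_pipeline(
        bundle.volume,
        bundle.nodule,
        model,
        vessel_mask=bundle.outer_vessels if use_true_outer_vessels else None,
        config=config,
        skip_continuity=skip_continuity,
    )
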