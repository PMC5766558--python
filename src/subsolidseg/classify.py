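"""Three-class voxel classification: training, operating point, initial labels.

The classifier is a k-nearest-neighbour model (k = 150 by default) over
z-scored features.  Its soft output — posterior probabilities ``P_v, P_c,
P_g`` per voxel — is turned into hard labels through class weights
``(w_v, w_c, w_g)`` that act as the operating point: the likelihood of class
``m`` is ``L_m(x) = w_m * P_m(x)`` and every nodule voxel receives
``argmax_m L_m(x)``.  The weights sum to 1 and are found by an exhaustive
grid search (step 0.01 on the simplex) minimizing hard-label disagreement on
out-of-fold posteriors from grouped (per-patient) cross-validation.

Training samples are balanced beforehand: each class is downsampled without
replacement to the minority-class size, drawing approximately equally from
every nodule.

Hard labeling is followed by a single solitary-voxel smoothing pass: a voxel
with no same-label neighbour in its masked 26-neighbourhood takes the
majority label of those neighbours.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.neighbors import KNeighborsClassifier

from .features import FeatureSpec
from .standardize import KernelBandProfile, identity_profile
from .volume import CORE, FOREGROUND_CLASSES, GROUND_GLASS, VESSEL, LabelMap, Volume

logger = logging.getLogger(__name__)

DEFAULT_K = 150
DEFAULT_GRID_STEP = 0.01

#: Argmax tie-break priority: ground-glass > vessel > core.
_TIE_PRIORITY = (GROUND_GLASS, VESSEL, CORE)
# column order of likelihood arrays is (v, c, g) = labels (1, 2, 3)
_PRIORITY_COLS = np.array([c - 1 for c in _TIE_PRIORITY])  # (2, 0, 1)


@dataclass
class ClassWeights:
    """Operating point ``(w_v, w_c, w_g)``: nonnegative, summing to 1."""

    w_v: float
    w_c: float
    w_g: float

    def __post_init__(self) -> None:
        vals = (self.w_v, self.w_c, self.w_g)
        if any(w < 0 for w in vals):
            raise ValueError(f"class weights must be nonnegative, got {vals}")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError(f"class weights must sum to 1, got {vals} (sum {sum(vals)})")

    def as_array(self) -> np.ndarray:
        return np.array([self.w_v, self.w_c, self.w_g])


#: The operating point reported for the full-cohort model.
REFERENCE_WEIGHTS = ClassWeights(0.23, 0.13, 0.64)
UNIFORM_WEIGHTS = ClassWeights(1 / 3, 1 / 3, 1 / 3)


@dataclass
class PosteriorStack:
    """Aligned probability maps ``(P_v, P_c, P_g)`` over a nodule mask.

    ``p`` has shape ``(3,) + grid_shape``; at every masked voxel the three
    probabilities are in [0, 1] and sum to 1 (tolerance 1e-6).
    """

    p: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.p.shape[0] != 3 or self.p.shape[1:] != self.mask.shape:
            raise ValueError(f"posterior stack shape {self.p.shape} does not match mask {self.mask.shape}")
        pm = self.p[:, self.mask]
        if pm.size and (pm.min() < -1e-9 or pm.max() > 1 + 1e-9):
            raise ValueError("posterior probabilities must lie in [0, 1]")
        if pm.size and np.max(np.abs(pm.sum(axis=0) - 1.0)) > 1e-6:
            raise ValueError("posterior probabilities must sum to 1 at every masked voxel")


def _waterfill_quota(available: np.ndarray, target: int) -> np.ndarray:
    """Allocate ``target`` draws across groups as equally as possible.

    Each group is capped at its availability; the equal share is computed over
    the groups that can still take samples (smallest groups first), and any
    remainder is redistributed one at a time to the least-allocated groups
    with spare capacity (ties by group order).
    """
    available = np.asarray(available, dtype=int)
    quota = np.zeros_like(available)
    target = min(int(target), int(available.sum()))
    order = np.argsort(available, kind="stable")
    remaining = target
    n_left = len(available)
    for gi in order:
        share = remaining // n_left
        take = min(available[gi], share)
        quota[gi] = take
        remaining -= take
        n_left -= 1
    while remaining > 0:
        spare = np.flatnonzero(quota < available)
        gi = spare[np.argmin(quota[spare], axis=0)]
        quota[gi] += 1
        remaining -= 1
    return quota


def balance_classes(
    values: np.ndarray,
    labels: np.ndarray,
    nodule_ids: np.ndarray,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Downsample every class to the minority-class size, stratified by nodule.

    Selection is without replacement; within each class the per-nodule quota
    is as equal as possible given what each nodule can supply.  Returns
    ``(values, labels, selected_indices)`` with rows in original order;
    deterministic under a fixed seed.
    """
    labels = np.asarray(labels)
    nodule_ids = np.asarray(nodule_ids)
    counts = {c: int(np.sum(labels == c)) for c in FOREGROUND_CLASSES}
    missing = [c for c, n in counts.items() if n == 0]
    if missing:
        raise ValueError(f"cannot balance: class(es) {missing} absent from the training samples")
    minority = min(counts.values())
    rng = np.random.default_rng(seed)
    selected: list[np.ndarray] = []
    for c in FOREGROUND_CLASSES:
        cls_idx = np.flatnonzero(labels == c)
        if len(cls_idx) == minority:
            selected.append(cls_idx)
            continue
        groups = np.unique(nodule_ids[cls_idx])
        avail = np.array([np.sum(nodule_ids[cls_idx] == g) for g in groups])
        quota = _waterfill_quota(avail, minority)
        for g, q in zip(groups, quota):
            pool = cls_idx[nodule_ids[cls_idx] == g]
            selected.append(rng.choice(pool, size=q, replace=False))
    idx = np.sort(np.concatenate(selected))
    return values[idx], labels[idx], idx


@dataclass
class TrainedModel:
    """A trained kNN voxel classifier plus everything needed to apply it.

    Carries the feature spec, per-feature standardization statistics (z-score
    location/scale from the training set), the class-weight operating point,
    and the kernel-normalization profile the training scans were passed
    through, so that test scans can be standardized symmetrically.
    """

    knn: KNeighborsClassifier
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    train_values_std: np.ndarray
    train_labels: np.ndarray
    k: int
    feature_spec: FeatureSpec = field(default_factory=FeatureSpec)
    weights: ClassWeights = field(default_factory=lambda: UNIFORM_WEIGHTS)
    band_profile: KernelBandProfile = field(default_factory=identity_profile)
    format_version: str = "subsolidseg-model-1"

    def predict_proba(self, values: np.ndarray) -> np.ndarray:
        """Posterior columns ``(P_v, P_c, P_g)`` = neighbour class fractions."""
        z = (values - self.feature_mean) / self.feature_scale
        proba = self.knn.predict_proba(z)
        out = np.zeros((values.shape[0], 3))
        for col, cls in enumerate(self.knn.classes_):
            out[:, int(cls) - 1] = proba[:, col]
        return out

    # -- serialization (directory of JSON sidecars + npy arrays) --------------

    def save(self, path: str) -> None:
        os.makedirs(path, exist_ok=True)
        meta = {
            "format_version": self.format_version,
            "k": self.k,
            "feature_spec": self.feature_spec.to_dict(),
            "weights": [self.weights.w_v, self.weights.w_c, self.weights.w_g],
            "band_profile": self.band_profile.to_dict(),
            "assumptions": {
                "feature_scaling": "z-score with training statistics",
                "distance": "euclidean",
            },
        }
        with open(os.path.join(path, "model.json"), "w") as f:
            json.dump(meta, f, indent=2)
        np.save(os.path.join(path, "feature_mean.npy"), self.feature_mean)
        np.save(os.path.join(path, "feature_scale.npy"), self.feature_scale)
        np.save(os.path.join(path, "train_X.npy"), self.train_values_std)
        np.save(os.path.join(path, "train_y.npy"), self.train_labels)

    @classmethod
    def load(cls, path: str) -> "TrainedModel":
        with open(os.path.join(path, "model.json")) as f:
            meta = json.load(f)
        mean = np.load(os.path.join(path, "feature_mean.npy"))
        scale = np.load(os.path.join(path, "feature_scale.npy"))
        X = np.load(os.path.join(path, "train_X.npy"))
        y = np.load(os.path.join(path, "train_y.npy"))
        knn = KNeighborsClassifier(n_neighbors=meta["k"], metric="euclidean").fit(X, y)
        return cls(
            knn=knn,
            feature_mean=mean,
            feature_scale=scale,
            train_values_std=X,
            train_labels=y,
            k=meta["k"],
            feature_spec=FeatureSpec.from_dict(meta["feature_spec"]),
            weights=ClassWeights(*meta["weights"]),
            band_profile=KernelBandProfile.from_dict(meta["band_profile"]),
            format_version=meta["format_version"],
        )


def train(
    values: np.ndarray,
    labels: np.ndarray,
    k: int = DEFAULT_K,
    feature_spec: FeatureSpec | None = None,
    band_profile: KernelBandProfile | None = None,
) -> TrainedModel:
    """Fit the kNN classifier on (balanced) samples.

    Features are z-scored with training statistics; neighbour search is
    Euclidean in the standardized space; the posterior for a class is the
    fraction of that class among the k nearest training samples.  ``k`` is
    clipped to the sample count with a warning when the training set is small.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    n = values.shape[0]
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of training samples ({n})")
    present = set(np.unique(labels).tolist())
    if not set(FOREGROUND_CLASSES) <= present:
        raise ValueError(f"training set must contain all three classes, got labels {sorted(present)}")
    mean = values.mean(axis=0)
    scale = values.std(axis=0)
    scale[scale < 1e-12] = 1.0
    z = (values - mean) / scale
    knn = KNeighborsClassifier(n_neighbors=k, metric="euclidean")
    knn.fit(z, labels)
    return TrainedModel(
        knn=knn,
        feature_mean=mean,
        feature_scale=scale,
        train_values_std=z,
        train_labels=labels.copy(),
        k=k,
        feature_spec=feature_spec or FeatureSpec(),
        band_profile=band_profile or identity_profile(),
    )


def clipped_k(k: int, n_train: int) -> int:
    """Clip k to n_train (logged); small phantom-scale sets cannot fill k=150."""
    if k > n_train:
        logger.warning("k=%d exceeds training size %d; clipping to %d", k, n_train, n_train)
        return n_train
    return k


def weight_grid(grid_step: float = DEFAULT_GRID_STEP) -> np.ndarray:
    """All weight triples on the simplex lattice with the given step.

    For step ``s = 1/N`` the candidates are ``(i, j, N-i-j)/N`` for all
    nonnegative integer pairs with ``i + j <= N`` (e.g. 6 points at step 0.5,
    5151 points at step 0.01).
    """
    N = int(round(1.0 / grid_step))
    if abs(N * grid_step - 1.0) > 1e-9:
        raise ValueError(f"grid_step must divide 1, got {grid_step}")
    pts = [
        (i / N, j / N, (N - i - j) / N)
        for i in range(N + 1)
        for j in range(N - i + 1)
    ]
    return np.array(pts)


def argmax_labels(likelihoods: np.ndarray) -> np.ndarray:
    """Hard labels from likelihood columns ``(L_v, L_c, L_g)``.

    Ties are broken by class priority ground-glass > vessel > core.
    """
    reordered = likelihoods[:, _PRIORITY_COLS]  # (g, v, c); argmax takes first max
    best = np.argmax(reordered, axis=1)
    return np.array(_TIE_PRIORITY)[best]


def optimize_weights(
    values: np.ndarray,
    labels: np.ndarray,
    groups: np.ndarray,
    k: int = DEFAULT_K,
    grid_step: float = DEFAULT_GRID_STEP,
    max_leave_one_out_groups: int = 25,
    n_folds_large: int = 10,
    seed: int = 0,
) -> ClassWeights:
    """Grid-search the class-weight operating point on out-of-fold posteriors.

    Cross-validation is grouped by patient: leave-one-group-out when there are
    few groups, seeded grouped K-fold otherwise.  For every simplex lattice
    point the hard labels ``argmax_m(w_m * P_m)`` are compared with the
    reference labels; the point with the fewest disagreements wins, ties going
    to the triple nearest uniform and then lexicographic order.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least two patient groups for cross-validation")
    if len(uniq) <= max_leave_one_out_groups:
        folds = [uniq[i : i + 1] for i in range(len(uniq))]
    else:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(uniq))
        folds = [uniq[perm[i::n_folds_large]] for i in range(n_folds_large)]

    posteriors = np.zeros((len(labels), 3))
    for fold_groups in folds:
        test = np.isin(groups, fold_groups)
        if not test.any():
            raise ValueError("empty cross-validation fold")
        train_idx = ~test
        model = train(values[train_idx], labels[train_idx], k=clipped_k(k, int(train_idx.sum())))
        posteriors[test] = model.predict_proba(values[test])

    return optimize_weights_from_posteriors(posteriors, labels, grid_step)


def optimize_weights_from_posteriors(
    posteriors: np.ndarray,
    labels: np.ndarray,
    grid_step: float = DEFAULT_GRID_STEP,
    class_balance_exponent: float = 0.0,
) -> ClassWeights:
    """Exhaustive simplex grid search given posterior columns ``(P_v,P_c,P_g)``.

    By default every sample counts equally (total disagreement).  With
    ``class_balance_exponent`` alpha > 0, a sample of class c is weighted by
    ``1 / n_c**alpha``, damping the dominance of large classes in the
    objective; alpha = 1 is fully class-balanced.
    """
    grid = weight_grid(grid_step)
    labels = np.asarray(labels)
    sample_w = np.ones(len(labels))
    if class_balance_exponent > 0:
        for c in FOREGROUND_CLASSES:
            n_c = int(np.sum(labels == c))
            if n_c:
                sample_w[labels == c] = 1.0 / n_c**class_balance_exponent
    best = None
    uniform = np.array([1 / 3, 1 / 3, 1 / 3])
    for w in grid:
        pred = argmax_labels(posteriors * w)
        disagree = float(np.sum(sample_w[pred != labels]))
        key = (round(disagree, 10), float(np.sum((w - uniform) ** 2)), tuple(w))
        if best is None or key < best[0]:
            best = (key, w)
    w = best[1]
    return ClassWeights(*w)


def predict_posteriors(
    model: TrainedModel,
    vol_std: Volume,
    mask_std: LabelMap | np.ndarray,
    source_grid: Volume | LabelMap | None = None,
) -> PosteriorStack:
    """Posterior maps on the standardized grid, optionally moved to the source grid.

    Posteriors are computed at every masked voxel of the standardized grid.
    When ``source_grid`` is given, each probability map is trilinearly
    interpolated onto that grid (node-aligned, matching origins) and the
    triple is renormalized to sum to 1.  Voxels outside the standardized mask
    borrow the value of the nearest masked voxel before interpolation, so the
    maps are well defined up to the mask boundary.
    """
    from .features import assemble_features

    mask_arr = mask_std.data > 0 if isinstance(mask_std, LabelMap) else np.asarray(mask_std) > 0
    fm = assemble_features(vol_std, mask_arr, model.feature_spec)
    proba = model.predict_proba(fm.values)

    stack = np.zeros((3,) + vol_std.shape)
    stack[2][...] = 1.0  # default: ground-glass outside the computed region
    flat_mask = mask_arr.ravel()
    for c in range(3):
        plane = stack[c].ravel()
        plane[flat_mask] = proba[:, c]
        stack[c] = plane.reshape(vol_std.shape)
    # propagate nearest masked value outward so interpolation at the mask
    # boundary does not mix in the background fill
    if not mask_arr.all():
        _, nearest = ndimage.distance_transform_edt(~mask_arr, return_indices=True)
        for c in range(3):
            stack[c] = stack[c][tuple(nearest)]

    if source_grid is None or (
        vol_std.shape == source_grid.shape
        and all(abs(a - b) < 1e-9 for a, b in zip(vol_std.spacing, source_grid.spacing))
    ):
        return PosteriorStack(stack, mask_arr, vol_std.spacing, vol_std.origin)

    # physical coverage check: every source voxel must map inside the
    # standardized grid extent (edge clamp tolerance of one voxel)
    for ax in range(3):
        src_extent = (source_grid.shape[ax] - 1) * source_grid.spacing[ax]
        std_extent = (vol_std.shape[ax] - 1) * vol_std.spacing[ax]
        if src_extent > std_extent + vol_std.spacing[ax]:
            raise ValueError(
                f"source grid extends {src_extent:.2f} mm along axis {ax} but the "
                f"standardized grid only covers {std_extent:.2f} mm"
            )
    coords = np.meshgrid(
        *[
            np.arange(n) * ss / ts
            for n, ss, ts in zip(source_grid.shape, source_grid.spacing, vol_std.spacing)
        ],
        indexing="ij",
    )
    out = np.stack(
        [ndimage.map_coordinates(stack[c], coords, order=1, mode="nearest") for c in range(3)]
    )
    out = np.clip(out, 0.0, None)
    out /= out.sum(axis=0, keepdims=True)
    src_mask = ndimage.map_coordinates(mask_arr.astype(np.uint8), coords, order=0, mode="nearest")
    return PosteriorStack(out, src_mask > 0, source_grid.spacing, source_grid.origin)


def likelihoods(post: PosteriorStack, weights: ClassWeights) -> np.ndarray:
    """Likelihood stack ``L_m = w_m * P_m``, shape ``(3,) + grid``."""
    return post.p * weights.as_array()[:, None, None, None]


def initial_segmentation(
    post: PosteriorStack,
    weights: ClassWeights,
    mask: np.ndarray | LabelMap | None = None,
    smooth: bool = True,
) -> LabelMap:
    """Initial three-class labels: per-voxel ``argmax_m(w_m * P_m)``.

    Followed (by default) by one solitary-voxel smoothing pass.  Voxels
    outside the mask stay background.
    """
    if mask is None:
        mask_arr = post.mask
    else:
        mask_arr = mask.data > 0 if isinstance(mask, LabelMap) else np.asarray(mask) > 0
    L = likelihoods(post, weights)
    flat = L.reshape(3, -1).T[mask_arr.ravel()]
    labels = np.zeros(post.mask.shape, dtype=np.int16)
    labels.ravel()[mask_arr.ravel()] = argmax_labels(flat)
    out = LabelMap(labels, post.spacing, post.origin)
    if smooth:
        out = smooth_solitary(out, mask_arr, L)
    return out


_NEIGH26 = np.ones((3, 3, 3))
_NEIGH26[1, 1, 1] = 0.0


def smooth_solitary(
    labels: LabelMap,
    mask: np.ndarray | None = None,
    likelihood_stack: np.ndarray | None = None,
) -> LabelMap:
    """Replace solitary voxels by the majority label of their neighbours.

    A masked voxel is solitary when no voxel in its 26-neighbourhood (within
    the mask) shares its label.  Replacement reads a snapshot of the input in
    a single lexicographic pass (no cascade).  Majority ties are broken by the
    largest summed likelihood among the tied classes when a likelihood stack
    is supplied, else by class priority ground-glass > vessel > core.
    """
    data = labels.data
    mask_arr = data > 0 if mask is None else np.asarray(mask) > 0
    snapshot = data.copy()
    same = np.zeros(data.shape)
    for c in FOREGROUND_CLASSES:
        is_c = ((snapshot == c) & mask_arr).astype(np.float64)
        cnt = ndimage.correlate(is_c, _NEIGH26, mode="constant", cval=0.0)
        same[snapshot == c] = cnt[snapshot == c]
    solitary = mask_arr & (snapshot > 0) & (same < 0.5)
    if not solitary.any():
        return labels.with_data(snapshot)
    out = snapshot.copy()
    shape = data.shape
    for z, y, x in np.argwhere(solitary):
        zl, zh = max(z - 1, 0), min(z + 2, shape[0])
        yl, yh = max(y - 1, 0), min(y + 2, shape[1])
        xl, xh = max(x - 1, 0), min(x + 2, shape[2])
        nb_labels = snapshot[zl:zh, yl:yh, xl:xh]
        nb_mask = mask_arr[zl:zh, yl:yh, xl:xh].copy()
        nb_mask[z - zl, y - yl, x - xl] = False
        votes = nb_labels[nb_mask]
        votes = votes[votes > 0]
        if votes.size == 0:
            continue  # isolated masked voxel: nothing to vote with
        counts = np.bincount(votes, minlength=4)[1:4]
        top = counts.max()
        tied = [c for c in FOREGROUND_CLASSES if counts[c - 1] == top]
        if len(tied) == 1 or likelihood_stack is None:
            choice = min(tied, key=lambda c: _TIE_PRIORITY.index(c)) if len(tied) > 1 else tied[0]
        else:
            sums = {
                c: float(likelihood_stack[c - 1, zl:zh, yl:yh, xl:xh][nb_mask & (nb_labels == c)].sum())
                for c in tied
            }
            best = max(sums.values())
            choice = min(
                (c for c in tied if sums[c] == best), key=lambda c: _TIE_PRIORITY.index(c)
            )
        out[z, y, x] = choice
    return labels.with_data(out)
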