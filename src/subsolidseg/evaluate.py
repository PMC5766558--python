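"""Detection and voxel-wise evaluation protocols.

Detection: a class is *detected* in a nodule when its label map contains a
26-connected component of two or more voxels (single stray voxels do not
count).  Detection agreement between two raters is summarized per class by a
2x2 table with accuracy, sensitivity, specificity, precision, and Cohen's
kappa with a 95% confidence interval from the asymptotic standard error.

Voxel scoring: per nodule and class, sensitivity ``|P∩R|/|R|``, precision
``|P∩R|/|P|`` and Dice ``2|P∩R|/(|P|+|R|)`` against a reference, either on
the axial slice with the largest nodule cross-section or in full 3D.  When
exactly one of prediction/reference is empty for a class (presence
disagreement) all three scores are zero for that nodule; when both are empty
the row is unscoreable and excluded from aggregates.  Consensus references
are built by intersecting two raters' segmentations, disagreeing voxels
falling back to ground-glass.  Summaries report mean and sample SD (ddof=1)
twice: over all scoreable nodules, and over the presence-agreement stratum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import FOREGROUND_CLASSES, GROUND_GLASS, LEGEND, LabelMap, require_same_grid

_STRUCT26 = ndimage.generate_binary_structure(3, 3)
MIN_DETECTION_VOXELS = 2


@dataclass
class DetectionRecord:
    """Per-nodule presence and component counts for the three classes."""

    nodule_id: object
    present: dict  # class -> bool
    component_count: dict  # class -> int


@dataclass
class AgreementMetrics:
    """2x2 agreement between two raters for one class."""

    kappa: float
    kappa_ci: tuple[float, float]
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    table: tuple[int, int, int, int]  # (tp, fp, fn, tn), rater a as reference


def detect_classes(labels: LabelMap, nodule_id=None) -> DetectionRecord:
    """Count qualifying 26-connected components per class.

    A component qualifies with >= 2 voxels; a class is present when at least
    one component qualifies.
    """
    present, counts = {}, {}
    for cls in FOREGROUND_CLASSES:
        lab, n = ndimage.label(labels.data == cls, structure=_STRUCT26)
        if n == 0:
            counts[cls] = 0
        else:
            sizes = np.bincount(lab.ravel())[1:]
            counts[cls] = int(np.sum(sizes >= MIN_DETECTION_VOXELS))
        present[cls] = counts[cls] >= 1
    return DetectionRecord(nodule_id=nodule_id, present=present, component_count=counts)


def agreement_from_table(tp: int, fp: int, fn: int, tn: int) -> AgreementMetrics:
    """All agreement metrics from a 2x2 table (rater a is the reference).

    kappa = (p_o - p_e) / (1 - p_e); the 95% CI uses the asymptotic standard
    error sqrt(p_o (1 - p_o) / (n (1 - p_e)^2)) with a normal approximation.
    Undefined ratios (empty margins, p_e = 1) come back as NaN.
    """
    n = tp + fp + fn + tn
    if n == 0:
        raise ValueError("empty agreement table")
    p_o = (tp + tn) / n
    p_e = ((tp + fn) / n) * ((tp + fp) / n) + ((tn + fp) / n) * ((tn + fn) / n)
    if abs(1.0 - p_e) < 1e-12:
        kappa, ci = float("nan"), (float("nan"), float("nan"))
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
        se = np.sqrt(p_o * (1.0 - p_o) / (n * (1.0 - p_e) ** 2))
        ci = (kappa - 1.96 * se, kappa + 1.96 * se)

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    return AgreementMetrics(
        kappa=kappa,
        kappa_ci=ci,
        accuracy=p_o,
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        precision=ratio(tp, tp + fp),
        table=(tp, fp, fn, tn),
    )


def pairwise_agreement(
    a: list[DetectionRecord], b: list[DetectionRecord]
) -> dict[int, AgreementMetrics]:
    """Per-class detection agreement between two raters (a = reference)."""
    ids_a = [r.nodule_id for r in a]
    ids_b = [r.nodule_id for r in b]
    if ids_a != ids_b:
        raise ValueError("detection records refer to different nodule sets")
    out = {}
    for cls in FOREGROUND_CLASSES:
        pa = np.array([r.present[cls] for r in a])
        pb = np.array([r.present[cls] for r in b])
        tp = int(np.sum(pa & pb))
        fp = int(np.sum(~pa & pb))
        fn = int(np.sum(pa & ~pb))
        tn = int(np.sum(~pa & ~pb))
        out[cls] = agreement_from_table(tp, fp, fn, tn)
    return out


def voxel_scores(
    pred: LabelMap, ref: LabelMap, plane: int | None = None, nodule_id=None
) -> pd.DataFrame:
    """Per-class sensitivity/precision/Dice of a prediction against a reference.

    ``plane`` restricts scoring to one axial slice; omit it for full-3D
    scoring.  Returns one row per class with the zero convention applied
    (presence disagreement -> all scores 0) and a ``scoreable`` flag
    (False when the class is absent from both maps).
    """
    require_same_grid(pred, ref, "prediction and reference")
    p_data, r_data = pred.data, ref.data
    if plane is not None:
        p_data, r_data = p_data[plane], r_data[plane]
    rows = []
    for cls in FOREGROUND_CLASSES:
        p = p_data == cls
        r = r_data == cls
        np_, nr = int(p.sum()), int(r.sum())
        inter = int((p & r).sum())
        if np_ == 0 and nr == 0:
            sens = prec = dsc = float("nan")
            scoreable = False
            agree = True
        elif np_ == 0 or nr == 0:
            sens = prec = dsc = 0.0
            scoreable = True
            agree = False
        else:
            sens = inter / nr
            prec = inter / np_
            dsc = 2.0 * inter / (np_ + nr)
            scoreable = True
            agree = True
        rows.append(
            {
                "nodule_id": nodule_id,
                "class": cls,
                "class_name": LEGEND[cls],
                "sensitivity": sens,
                "precision": prec,
                "dsc": dsc,
                "n_pred": np_,
                "n_ref": nr,
                "scoreable": scoreable,
                "presence_agreement": agree,
            }
        )
    return pd.DataFrame(rows)


def consensus_intersection(a: LabelMap, b: LabelMap, nodule: np.ndarray | LabelMap | None = None) -> LabelMap:
    """Consensus standard: voxels two raters label identically.

    Inside the nodule, voxels the raters disagree on fall back to
    ground-glass (the nodule's default tissue); outside they stay background.
    """
    require_same_grid(a, b, "rater label maps")
    if nodule is None:
        nod = (a.data > 0) | (b.data > 0)
    else:
        nod = nodule.data > 0 if isinstance(nodule, LabelMap) else np.asarray(nodule) > 0
    out = np.where(a.data == b.data, a.data, 0).astype(np.int16)
    out[nod & (out == 0)] = GROUND_GLASS
    out[~nod] = 0
    return LabelMap(out, a.spacing, a.origin)


def largest_area_slice(nodule: LabelMap) -> int:
    """Axial index of the slice with the largest nodule cross-section.

    Ties go to the smallest index (``argmax`` first occurrence).
    """
    counts = (nodule.data > 0).sum(axis=(1, 2))
    if counts.sum() == 0:
        raise ValueError("empty nodule mask: no slice to select")
    return int(np.argmax(counts))


def stratified_summary(rows: pd.DataFrame) -> pd.DataFrame:
    """Means and sample SDs per class, over all scoreable rows and over the
    presence-agreement stratum, with n reported per cell.

    Empty strata yield NaN cells (undefined, not zero).
    """
    out = []
    for cls, grp in rows.groupby("class"):
        scoreable = grp[grp["scoreable"]]
        agree = scoreable[scoreable["presence_agreement"]]
        for stratum, sub in (("all", scoreable), ("presence-agreement", agree)):
            rec = {"class": cls, "class_name": LEGEND[int(cls)], "stratum": stratum, "n": len(sub)}
            for m in ("sensitivity", "precision", "dsc"):
                rec[f"{m}_mean"] = float(sub[m].mean()) if len(sub) else float("nan")
                rec[f"{m}_sd"] = float(sub[m].std(ddof=1)) if len(sub) > 1 else (0.0 if len(sub) == 1 else float("nan"))
            out.append(rec)
    return pd.DataFrame(out)


def select_evaluable(manifest: list[dict], min_diameter_mm: float = 6.0) -> list[dict]:
    """Apply the cohort inclusion filter to a nodule manifest.

    Excludes nodules smaller than ``min_diameter_mm`` (high chance of benign
    lesions) and nodules flagged ``complex`` (irregular, bubble-containing
    morphology outside the method's three-class scope).
    """
    return [
        m
        for m in manifest
        if m.get("diameter_mm", np.inf) >= min_diameter_mm and not m.get("complex", False)
    ]
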