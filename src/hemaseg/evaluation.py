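"""Segmentation metrics and study harnesses.

Implements the evaluation side of the pipeline: Dice / IoU / pixel
accuracy, the symmetric Hausdorff distance in millimetres, maximum lesion
diameter measurement, tumor-size stratification (Tiny < 10 mm,
Small [10, 20) mm, Big >= 20 mm), per-stratum reporting, and the ablation
table machinery that toggles the transfer / Gaussian-attention / wavelet
components independently.

Conventions (documented in docs/methods.md): when truth and prediction are
both empty the case counts as perfect (Dice = IoU = ACC = 100) and the
Hausdorff distance is reported as missing; accuracy is plain pixel accuracy
over the full frame; the Hausdorff distance is the maximum (100th
percentile) boundary-to-boundary distance on 2-D slices, scaled by the
pixel spacing, with HD95 available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ShapeMismatchError

STRATA = ("Tiny", "Small", "Big")

#: Half-open stratum intervals in mm: [0, 10), [10, 20), [20, inf)
_STRATUM_EDGES = (10.0, 20.0)


def stratum_of(diameter_mm: float) -> str:
    """Map a maximum lesion diameter to its size stratum."""
    if diameter_mm < 0:
        raise ValueError(f"negative diameter: {diameter_mm}")
    if diameter_mm < _STRATUM_EDGES[0]:
        return "Tiny"
    if diameter_mm < _STRATUM_EDGES[1]:
        return "Small"
    return "Big"


def stratify(diameters_mm) -> list:
    return [stratum_of(d) for d in diameters_mm]


def _check_pair(truth: np.ndarray, pred: np.ndarray):
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape != pred.shape:
        raise ShapeMismatchError(f"mask shapes differ: {truth.shape} vs {pred.shape}")
    return truth.astype(bool), pred.astype(bool)


def dice_iou_acc(truth, pred) -> tuple:
    """(Dice, IoU, ACC) in percent for a pair of aligned binary masks."""
    t, p = _check_pair(truth, pred)
    inter = np.count_nonzero(t & p)
    st, sp = np.count_nonzero(t), np.count_nonzero(p)
    union = st + sp - inter
    if st == 0 and sp == 0:
        dice = iou = 100.0
    else:
        dice = 200.0 * inter / (st + sp)
        iou = 100.0 * inter / union
    acc = 100.0 * np.count_nonzero(t == p) / t.size
    return dice, iou, acc


def boundary_pixels(mask) -> np.ndarray:
    """Boolean map of boundary pixels: mask minus its erosion.

    A single isolated pixel is its own boundary.
    """
    m = np.asarray(mask).astype(bool)
    if not m.any():
        return m
    return m & ~ndimage.binary_erosion(m)


def hausdorff_mm(truth, pred, spacing, percentile: float = 100.0) -> float:
    """Symmetric Hausdorff distance between mask boundaries, in mm.

    Distances are Euclidean between pixel centres scaled by ``spacing``
    (row, col). Returns NaN when either mask is empty. ``percentile`` = 95
    gives the HD95 robust variant.
    """
    t, p = _check_pair(truth, pred)
    if not t.any() or not p.any():
        return float("nan")
    bt, bp = boundary_pixels(t), boundary_pixels(p)
    # exact Euclidean distance-to-nearest-boundary via the EDT of the complement
    dt_to_p = ndimage.distance_transform_edt(~bp, sampling=spacing)
    dt_to_t = ndimage.distance_transform_edt(~bt, sampling=spacing)
    d_tp = dt_to_p[bt]
    d_pt = dt_to_t[bp]
    if percentile >= 100.0:
        return float(max(d_tp.max(), d_pt.max()))
    return float(max(np.percentile(d_tp, percentile), np.percentile(d_pt, percentile)))


def max_diameter_mm(mask, spacing) -> float:
    """Maximum pairwise distance between boundary pixel centres, in mm.

    ``mask`` must be a nonempty (single-component) binary array; a single
    pixel has diameter 0.
    """
    m = np.asarray(mask).astype(bool)
    if not m.any():
        raise ValueError("empty mask component")
    pts = np.argwhere(boundary_pixels(m)).astype(float) * np.asarray(spacing, dtype=float)
    if len(pts) == 1:
        return 0.0
    # reduce the candidate set to the convex extremes along many directions
    # only when large; otherwise all-pairs is cheap and exact
    if len(pts) > 2000:
        from scipy.spatial import ConvexHull

        pts = pts[ConvexHull(pts).vertices]
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


@dataclass
class MetricsReport:
    """Aggregate segmentation metrics, overall and per size stratum."""

    dice: float
    hd_mm: float
    iou: float
    acc: float
    per_stratum: dict = field(default_factory=dict)
    n_cases: dict = field(default_factory=dict)
    n_missing_hd: int = 0

    def to_dict(self) -> dict:
        return {
            "dice": self.dice, "hd_mm": self.hd_mm, "iou": self.iou, "acc": self.acc,
            "per_stratum": dict(self.per_stratum), "n_cases": dict(self.n_cases),
            "n_missing_hd": self.n_missing_hd,
        }


def case_metrics(truth, pred, spacing) -> dict:
    dice, iou, acc = dice_iou_acc(truth, pred)
    return {"dice": dice, "iou": iou, "acc": acc,
            "hd_mm": hausdorff_mm(truth, pred, spacing)}


def evaluate_model(model, cases) -> MetricsReport:
    """Evaluate a predictor on phantom cases.

    ``model`` is either a callable mapping a case to a binary mask or an
    object with a ``predict(case)`` method (e.g. a trained pipeline). The
    case stratum is the stratum of its largest lesion.
    """
    if not cases:
        raise ValueError("empty case list")
    predict = model.predict if hasattr(model, "predict") else model
    rows = []
    for case in cases:
        pred = np.asarray(predict(case)).astype(bool)
        m = case_metrics(case.mask, pred, case.noncontrast.spacing[-2:])
        if case.tumor_records:
            m["stratum"] = max(case.tumor_records, key=lambda r: r.diameter_mm).stratum
        else:
            m["stratum"] = None
        rows.append(m)
    df = pd.DataFrame(rows)
    hd_valid = df["hd_mm"].dropna()
    per_stratum = {
        s: float(df.loc[df["stratum"] == s, "dice"].mean())
        for s in STRATA if (df["stratum"] == s).any()
    }
    n_cases = {s: int((df["stratum"] == s).sum()) for s in STRATA}
    return MetricsReport(
        dice=float(df["dice"].mean()),
        hd_mm=float(hd_valid.mean()) if len(hd_valid) else float("nan"),
        iou=float(df["iou"].mean()),
        acc=float(df["acc"].mean()),
        per_stratum=per_stratum,
        n_cases=n_cases,
        n_missing_hd=int(df["hd_mm"].isna().sum()),
    )


def ablation_table(train_cases, eval_cases, configs, seeds,
                   model_config=None, train_config=None) -> pd.DataFrame:
    """Train and evaluate one model per component-flag combination per seed.

    ``configs`` is a list of dicts with boolean keys ``transfer``, ``gpsa``,
    ``weem``. Returns one row per combination with mean +/- sd metrics
    across seeds.
    """
    from . import training  # deferred: training pulls in the network stack

    if not configs:
        raise ValueError("no ablation configurations given")
    rows = []
    for flags in configs:
        per_seed = []
        for seed in seeds:
            pipeline = training.run_protocol(
                train_cases, flags=flags, seed=seed,
                model_config=model_config, train_config=train_config,
            )
            report = evaluate_model(pipeline, eval_cases)
            per_seed.append(report)
        row = {"transfer": flags["transfer"], "gpsa": flags["gpsa"], "weem": flags["weem"]}
        for metric in ("dice", "hd_mm", "iou", "acc"):
            vals = np.array([getattr(r, metric) for r in per_seed], dtype=float)
            row[f"{metric}_mean"] = float(np.nanmean(vals))
            row[f"{metric}_sd"] = float(np.nanstd(vals))
        rows.append(row)
    return pd.DataFrame(rows)


def full_ablation_design() -> list:
    """The eight on/off combinations of {transfer, gpsa, weem}."""
    return [
        {"transfer": t, "gpsa": g, "weem": w}
        for t in (False, True) for g in (False, True) for w in (False, True)
    ]
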