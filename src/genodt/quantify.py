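"""LGE-style substrate quantification and VT-location prediction metrics.

Pipeline: Otsu thresholding binarizes the masked myocardium intensities into
low- and high-intensity classes; the mean and SD of the low-intensity class
define the non-fibrotic reference; voxels >= reference mean + 4 SD are dense
scar (DS), voxels in [mean + 2 SD, mean + 4 SD) are diffuse fibrosis (DF),
everything else is non-fibrotic myocardium.  Regional remodeling amounts are
expressed as percentages of the total tissue volume; prediction quality of
region-level VT localization is summarized by the standard confusion-matrix
metrics (sensitivity, specificity, accuracy, error rate, F1, MCC).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SegmentationResult", "PredictionMetrics",
    "otsu_threshold", "classify_remodeling", "regional_fractions",
    "correlate_features", "prediction_metrics",
]


class SegmentationError(ValueError):
    pass


@dataclass
class SegmentationResult:
    otsu_threshold: float
    ref_mean: float
    ref_sd: float
    scar_mask: np.ndarray      # bool, image shape
    fibrosis_mask: np.ndarray  # bool, image shape
    myocardium_mask: np.ndarray


@dataclass(frozen=True)
class PredictionMetrics:
    sensitivity: float
    specificity: float
    accuracy: float
    error_rate: float
    f1: float
    mcc: float
    tp: int
    fp: int
    fn: int
    tn: int


def otsu_threshold(intensities: np.ndarray) -> float:
    """Exact Otsu threshold of a 1D intensity sample.

    Evaluates the between-class variance at every distinct intensity value
    and returns the threshold t maximizing it, where the low class is
    {x <= t}.  The returned t is the midpoint between the optimal cut's
    boundary values, so classification is robust to float comparison.
    """
    x = np.sort(np.asarray(intensities, dtype=np.float64).ravel())
    vals = np.unique(x)
    if len(vals) < 2:
        raise SegmentationError("degenerate histogram: constant image")
    n = len(x)
    csum = np.cumsum(x)
    total = csum[-1]
    # candidate cuts after each distinct value except the last
    idx = np.searchsorted(x, vals[:-1], side="right")
    w0 = idx / n
    w1 = 1.0 - w0
    mu0 = csum[idx - 1] / idx
    mu1 = (total - csum[idx - 1]) / (n - idx)
    sb = w0 * w1 * (mu0 - mu1) ** 2
    k = int(np.argmax(sb))
    return float(0.5 * (vals[k] + vals[k + 1]))


def classify_remodeling(image: np.ndarray, myocardium_mask: np.ndarray,
                        scar_sd: float = 4.0, fibrosis_sd: float = 2.0
                        ) -> SegmentationResult:
    """Segment dense scar and diffuse fibrosis from an LGE-like image.

    The low-intensity Otsu class provides the reference statistics; scar is
    intensity >= ref_mean + scar_sd * ref_sd (inclusive), fibrosis is the
    band [ref_mean + fibrosis_sd * ref_sd, scar threshold).
    """
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(myocardium_mask, dtype=bool)
    if image.shape != mask.shape:
        raise SegmentationError("image and mask shapes differ")
    vals = image[mask]
    if vals.size < 2:
        raise SegmentationError("myocardium mask too small")
    t = otsu_threshold(vals)
    low = vals[vals <= t]
    ref_mean = float(low.mean())
    ref_sd = float(low.std(ddof=0))
    if ref_sd == 0.0:
        raise SegmentationError("reference class has zero variance")
    scar_thr = ref_mean + scar_sd * ref_sd
    fib_thr = ref_mean + fibrosis_sd * ref_sd
    scar = mask & (image >= scar_thr)
    fib = mask & (image >= fib_thr) & (image < scar_thr)
    return SegmentationResult(
        otsu_threshold=t, ref_mean=ref_mean, ref_sd=ref_sd,
        scar_mask=scar, fibrosis_mask=fib, myocardium_mask=mask)


def regional_fractions(seg: SegmentationResult, region_map: np.ndarray,
                       region_ids=None):
    """Per-region DF/DS/TFV as percent of total tissue volume.

    Normalization follows the whole-tissue convention: each region's
    remodeling volume is divided by the TOTAL myocardium volume, so the
    DS (or DF) fractions sum over regions to the global fraction.
    Returns a pandas DataFrame indexed by region id with columns
    DF_pct, DS_pct, TFV_pct.
    """
    import pandas as pd
    import warnings

    region_map = np.asarray(region_map)
    mask = seg.myocardium_mask
    total = int(mask.sum())
    if total == 0:
        raise SegmentationError("empty myocardium mask")
    if region_ids is None:
        region_ids = sorted(int(r) for r in np.unique(region_map[mask]) if r > 0)
    rows = []
    for rid in region_ids:
        rmask = mask & (region_map == rid)
        if not rmask.any():
            warnings.warn(f"region {rid} is empty; fractions set to 0")
            rows.append((rid, 0.0, 0.0, 0.0))
            continue
        df = 100.0 * float((seg.fibrosis_mask & rmask).sum()) / total
        ds = 100.0 * float((seg.scar_mask & rmask).sum()) / total
        rows.append((rid, df, ds, df + ds))
    out = pd.DataFrame(rows, columns=["region", "DF_pct", "DS_pct", "TFV_pct"])
    return out.set_index("region")


def correlate_features(table, strict: bool = True):
    """Pairwise Pearson correlation matrix of a features table.

    ``table``: DataFrame (or dict of equal-length arrays) whose columns are
    the variables, e.g. per-region DF/DS/TFV volumes and VT counts.
    Zero-variance variables yield NaN correlations (flagged via warning).
    Also attaches a categorical label per the conventional reading:
    |r| > 0.7 high, 0.5 < |r| <= 0.7 moderate, else low/none.
    """
    import pandas as pd
    import warnings

    df = pd.DataFrame(table)
    if len(df) < 3:
        raise ValueError("need at least 3 observations for correlations")
    zero_var = [c for c in df.columns if df[c].std(ddof=0) == 0]
    if zero_var:
        warnings.warn(f"zero-variance variables, r undefined: {zero_var}")
    r = df.corr(method="pearson")
    labels = r.map(lambda v: "high" if abs(v) > 0.7 else
                   ("moderate" if abs(v) > 0.5 else "low")
                   if np.isfinite(v) else "undefined")
    r.attrs["labels"] = labels
    return r


def prediction_metrics(predicted_regions, observed_regions,
                       all_regions) -> PredictionMetrics:
    """Region-level VT-location prediction quality.

    predicted_regions / observed_regions: per case, a set of region labels
    (pass a list of sets for several cases; a single set is treated as one
    case).  Decisions are pooled across (case x region) into one confusion
    matrix.
    """
    all_regions = list(all_regions)
    if not all_regions:
        raise ValueError("empty region universe")
    if isinstance(predicted_regions, (set, frozenset)):
        predicted_regions = [predicted_regions]
    if isinstance(observed_regions, (set, frozenset)):
        observed_regions = [observed_regions]
    if len(predicted_regions) != len(observed_regions):
        raise ValueError("predicted and observed case counts differ")
    tp = fp = fn = tn = 0
    for pred, obs in zip(predicted_regions, observed_regions):
        pred, obs = set(pred), set(obs)
        for r in all_regions:
            if r in pred and r in obs:
                tp += 1
            elif r in pred:
                fp += 1
            elif r in obs:
                fn += 1
            else:
                tn += 1
    n = tp + fp + fn + tn
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / n
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else float("nan")
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = ((tp * tn - fp * fn) / denom) if denom else float("nan")
    return PredictionMetrics(
        sensitivity=sens, specificity=spec, accuracy=acc,
        error_rate=1.0 - acc, f1=f1, mcc=mcc, tp=tp, fp=fp, fn=fn, tn=tn)
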