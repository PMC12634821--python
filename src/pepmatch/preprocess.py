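"""Intensity transforms, fold changes and noise filtering.

Both platforms' intensities are log2-transformed and centered on the
per-sample (per condition column) mean, so that the fold change of a peak or
peptide is simply ``normalized_log2[treated] - normalized_log2[control]``
and the two platforms become comparable despite arbitrary global scale.
Centering on the mean of log2 values divides by the geometric mean of the
raw intensities; an arithmetic-mean variant is available via configuration.

The noise cutoff follows the sorted-intensity-curve picture: peaks sorted
from highest to lowest intensity trace a curve whose bend ("knee", the
operational inflection point) separates signal plateau from noise tail.  The
knee is the point of maximum perpendicular distance between the descending
log2-intensity curve and the chord joining its endpoints, computed on axes
normalized to [0, 1] — deterministic and parameter-free.  Peaks below the
knee intensity define the noise floor (their median intensity), which in
turn defines each peak's signal-to-noise ratio for the S/N filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError

logger = logging.getLogger(__name__)


@dataclass
class NormalizedTable:
    """Log2-normalized intensities with per-condition centering constants.

    ``df`` carries one ``norm_<condition>`` column per condition plus
    ``fold_change`` (treated minus control, NaN when either side is
    missing).  ``means`` retains the subtracted per-condition log2 means as
    provenance.
    """

    df: pd.DataFrame
    conditions: tuple[str, str]
    means: dict[str, float] = field(default_factory=dict)


def log2_normalize(
    df: pd.DataFrame,
    conditions: Sequence[str],
    method: str = "geometric",
    pseudocount: float = 0.0,
) -> NormalizedTable:
    """Log2-transform intensity columns and center each on its sample mean.

    Zeros and missing cells are excluded (treated as missing) unless a
    positive ``pseudocount`` is configured, in which case it is added to
    every value before the log.  With ``method="geometric"`` (default) the
    per-condition mean of the log2 values is subtracted, so each output
    column has mean 0 over its non-missing rows; ``method="arithmetic"``
    divides raw values by the arithmetic mean before the log instead.
    """
    conditions = tuple(conditions)
    out = df.copy()
    means: dict[str, float] = {}
    for cond in conditions:
        vals = pd.to_numeric(out[cond], errors="coerce").astype(float)
        if pseudocount > 0:
            vals = vals + pseudocount
        vals = vals.where(vals > 0)  # zeros/negatives -> missing
        if vals.notna().sum() == 0:
            raise DegenerateInputError(
                f"condition {cond!r}: no positive intensities to normalize"
            )
        if method == "geometric":
            logv = np.log2(vals)
            mean = float(logv.mean())
            out[f"norm_{cond}"] = logv - mean
        elif method == "arithmetic":
            mean_raw = float(vals.mean())
            out[f"norm_{cond}"] = np.log2(vals / mean_raw)
            mean = float(np.log2(mean_raw))
        else:
            raise ValueError(f"unknown normalization method {method!r}")
        means[cond] = mean
    treated, control = conditions[0], conditions[1]
    out["fold_change"] = out[f"norm_{treated}"] - out[f"norm_{control}"]
    return NormalizedTable(df=out, conditions=(treated, control), means=means)


def delta_fold_change(fc_maldi: float, fc_lcms: float) -> float:
    """Signed difference of platform fold changes, the input of Metric 1.

    Returns NaN (the "undefined" marker) when either fold change is missing;
    callers flag such candidates rather than dropping them.
    """
    if fc_maldi is None or fc_lcms is None:
        return float("nan")
    if not (np.isfinite(fc_maldi) and np.isfinite(fc_lcms)):
        return float("nan")
    return float(fc_maldi) - float(fc_lcms)


@dataclass
class NoiseModel:
    """Knee-based noise cutoff for a set of peak intensities.

    ``curve`` is the intensity vector sorted descending; ``knee_index`` is
    the position of the cutoff on that curve (None when no cutoff exists);
    ``intensity_threshold`` is the intensity at the knee (the minimum of the
    curve when there is no knee); ``noise_floor`` divides intensities into
    S/N ratios.
    """

    curve: np.ndarray
    knee_index: int | None
    intensity_threshold: float
    noise_floor: float

    @property
    def has_cutoff(self) -> bool:
        return self.knee_index is not None

    def snr(self, intensities: np.ndarray | Sequence[float]) -> np.ndarray:
        return np.asarray(intensities, dtype=float) / self.noise_floor


def knee_cutoff(intensities: Sequence[float]) -> NoiseModel:
    """Locate the noise cutoff on the sorted-intensity curve.

    The intensities are sorted descending, log2-transformed, and both axes
    rescaled to [0, 1]; the knee is the argmax of perpendicular distance to
    the chord from the first to the last point.  Degenerate curves (fewer
    than 3 distinct positive values, constant, or exactly linear so the
    chord coincides with the curve) yield a no-cutoff model: threshold at
    the minimum, nothing filtered, and a logged warning.
    """
    arr = np.asarray(intensities, dtype=float)
    arr = arr[np.isfinite(arr) & (arr > 0)]
    curve = np.sort(arr)[::-1]
    n = len(curve)

    def _no_cutoff(reason: str) -> NoiseModel:
        logger.warning("knee_cutoff: %s; no noise cutoff applied", reason)
        threshold = float(curve.min()) if n else 0.0
        floor = float(curve[curve > 0].min()) if n and (curve > 0).any() else 1.0
        return NoiseModel(
            curve=curve, knee_index=None,
            intensity_threshold=threshold, noise_floor=floor,
        )

    if n < 3 or len(np.unique(curve)) < 3:
        return _no_cutoff("fewer than 3 distinct positive intensities")

    y = np.log2(curve)
    x = np.arange(n, dtype=float)
    # normalize both axes to [0, 1]; y is non-constant here
    xs = x / (n - 1)
    ys = (y - y[-1]) / (y[0] - y[-1])
    # perpendicular distance of each point to the chord (xs0,ys0)-(xs1,ys1)
    dx, dy = xs[-1] - xs[0], ys[-1] - ys[0]
    dist = np.abs(dy * (xs - xs[0]) - dx * (ys - ys[0])) / np.hypot(dx, dy)
    k = int(np.argmax(dist))
    if dist[k] <= 1e-9:
        return _no_cutoff("curve is linear (chord coincides with curve)")

    threshold = float(curve[k])
    below = curve[curve < threshold]
    if below.size:
        floor = float(np.median(below))
    else:
        floor = float(curve.min())
    return NoiseModel(
        curve=curve, knee_index=k,
        intensity_threshold=threshold, noise_floor=floor,
    )


def snr_filter(
    table: pd.DataFrame,
    noise_model: NoiseModel,
    min_snr: float,
    intensity_column: str = "maldi_intensity",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition rows into (kept, removed) by peak signal-to-noise ratio.

    A row is kept iff ``intensity / noise_floor >= min_snr`` (boundary
    inclusive).  ``min_snr == 0`` keeps everything.
    """
    if not noise_model.noise_floor > 0:
        raise DegenerateInputError("noise floor must be positive for S/N filtering")
    snr = noise_model.snr(table[intensity_column].to_numpy(dtype=float))
    keep = snr >= min_snr
    return table[keep].copy(), table[~keep].copy()


def knee_filter(
    table: pd.DataFrame,
    noise_model: NoiseModel,
    intensity_column: str = "maldi_intensity",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition rows into (kept, removed) by the knee intensity threshold.

    With no cutoff (degenerate curve) everything is kept.  The boundary is
    inclusive: a peak exactly at the knee intensity survives.
    """
    if not noise_model.has_cutoff:
        return table.copy(), table.iloc[0:0].copy()
    vals = table[intensity_column].to_numpy(dtype=float)
    keep = vals >= noise_model.intensity_threshold
    return table[keep].copy(), table[~keep].copy()
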