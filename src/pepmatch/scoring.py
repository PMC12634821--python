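"""Candidate scoring and ranking: three bounded metrics plus the
automated top-differential (Metric 4) selection.

Each candidate (MALDI peak, peptide) receives three scores on a common
bounded scale:

* Metric 1 — fold-change concordance.  A Gaussian
  ``A * exp(-x^2 / (2 sigma^2))`` of the delta log2 fold change
  ``x = fc_MALDI - fc_LCMS``, amplitude A = 10 centered at 0; sigma is the
  sample SD of ALL defined deltas in the filtered match table, estimated
  once globally.  A peptide whose spatial abundance change agrees across
  platforms scores near 10.
* Metric 2 — mass agreement.  A falling sigmoid
  ``100 / (1 + exp(k (|dm| - x0)))`` with k = 10, x0 = 0.5 Da: sub-0.1 Da
  errors score near 100, errors near the 1 Da tolerance score near 0.  The absolute
  delta mass is used by default (sign carries no information about
  agreement); a config flag restores the literal signed form.
* Metric 3 — MALDI intensity.  A rising sigmoid
  ``5 / (1 + exp(-k (x - c)))`` with k = 1 and center c = 2 of the
  normalized log2 mean MALDI intensity, giving modest weight to signal
  strength.

The Peptide Score is the sum (bounded by 10 + 100 + 5 = 115); candidates
are ranked by it within each MALDI peak and, separately, within each
protein (accession) group — ranking inside the protein group is often the
more selective view.  Metric 4 automates the final image-level selection:
among the most abundant peaks (top quartile of mean normalized intensity),
take the n with the largest absolute fold change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError

logger = logging.getLogger(__name__)

SIGMA_FLOOR = 1e-6


def estimate_sigma(deltas) -> float:
    """Sample SD (n-1 denominator) of all defined delta log2 fold changes.

    Values that are NaN are excluded; fewer than two defined deltas is a
    degenerate input.  A near-zero spread is clamped to ``SIGMA_FLOOR`` with
    a warning so Metric 1 stays defined.
    """
    arr = np.asarray(deltas, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise DegenerateInputError(
            f"need >= 2 defined fold-change deltas to estimate sigma, got {arr.size}"
        )
    sigma = float(np.std(arr, ddof=1))
    if sigma < SIGMA_FLOOR:
        logger.warning("sigma %.3g below floor; clamped to %.0e", sigma, SIGMA_FLOOR)
        sigma = SIGMA_FLOOR
    return sigma


def metric1_score(x, sigma: float, amplitude: float = 10.0, center: float = 0.0):
    """Gaussian fold-change-concordance score, max ``amplitude`` at x=center."""
    if not sigma > 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    x = np.asarray(x, dtype=float)
    out = amplitude * np.exp(-((x - center) ** 2) / (2.0 * sigma**2))
    return float(out) if out.ndim == 0 else out


def metric2_score(
    delta_mass,
    scale: float = 100.0,
    steepness: float = 10.0,
    center: float = 0.5,
    signed: bool = False,
):
    """Sigmoid mass-agreement score; |delta m| = center scores scale/2.

    ``signed=False`` (default) scores the magnitude of the mass error;
    ``signed=True`` applies the sigmoid to the signed delta, in which case
    negative errors score above scale/2 regardless of magnitude.
    """
    x = np.asarray(delta_mass, dtype=float)
    if not signed:
        x = np.abs(x)
    out = scale / (1.0 + np.exp(steepness * (x - center)))
    return float(out) if out.ndim == 0 else out


def metric3_score(
    intensity, maximum: float = 5.0, steepness: float = 1.0, center: float = 2.0
):
    """Rising sigmoid intensity score in (0, maximum), half-max at ``center``."""
    x = np.asarray(intensity, dtype=float)
    out = maximum / (1.0 + np.exp(-steepness * (x - center)))
    return float(out) if out.ndim == 0 else out


def _rank_within(df: pd.DataFrame, group_col: str) -> pd.Series:
    """1-based rank by score within ``group_col`` with deterministic tie-break:
    total desc, |delta_mass| asc, MALDI intensity desc, accession, sequence."""
    order = df.sort_values(
        by=["total_score", "_abs_dm", "maldi_intensity", "accession", "sequence"],
        ascending=[False, True, False, True, True],
        kind="stable",
    )
    ranks = order.groupby(group_col, sort=False).cumcount() + 1
    return ranks.reindex(df.index)


def score_and_rank(candidates: pd.DataFrame, sigma: float, config) -> pd.DataFrame:
    """Score every candidate and rank within each peak and protein group.

    ``candidates`` must carry ``delta_mass``, ``delta_fold_change`` (NaN
    allowed) and ``maldi_intensity_norm`` (normalized log2 mean MALDI
    intensity).  Candidates with an undefined delta fold change receive
    metric1 = 0 and ``metric1_unavailable=True`` — flagged, not dropped.
    Output ordering is deterministic for any input row order.
    """
    df = candidates.copy()
    if len(df) == 0:
        for col in ("metric1", "metric2", "metric3", "total_score",
                    "rank_within_peak", "rank_within_protein_group"):
            df[col] = pd.Series(dtype=float)
        df["metric1_unavailable"] = pd.Series(dtype=bool)
        return df

    dfc = df["delta_fold_change"].to_numpy(dtype=float)
    unavailable = ~np.isfinite(dfc)
    m1 = np.where(
        unavailable,
        0.0,
        metric1_score(np.where(unavailable, 0.0, dfc), sigma,
                      amplitude=config.metric1_amplitude,
                      center=config.metric1_center),
    )
    m2 = metric2_score(
        df["delta_mass"].to_numpy(dtype=float),
        scale=config.metric2_scale,
        steepness=config.metric2_steepness,
        center=config.metric2_center,
        signed=config.signed_metric2,
    )
    m3 = metric3_score(
        df["maldi_intensity_norm"].to_numpy(dtype=float),
        maximum=config.metric3_max,
        steepness=config.metric3_steepness,
        center=config.metric3_center,
    )
    df["metric1"] = m1
    df["metric1_unavailable"] = unavailable
    df["metric2"] = m2
    df["metric3"] = m3
    df["total_score"] = m1 + m2 + m3

    df["_abs_dm"] = df["delta_mass"].abs()
    df["rank_within_peak"] = _rank_within(df, "peak_id")
    df["rank_within_protein_group"] = _rank_within(df, "accession")
    df = df.drop(columns="_abs_dm")
    # canonical output order: by peak m/z then rank
    df = df.sort_values(
        by=["mz", "rank_within_peak"], kind="stable"
    ).reset_index(drop=True)
    return df


@dataclass
class Metric4Selection:
    """Automated differential selection: the n most differential peaks among
    the most abundant ones."""

    peak_ids: list = field(default_factory=list)
    table: pd.DataFrame | None = None
    n_requested: int = 10
    abundance_cutoff: float = float("nan")


def metric4_top_differential(
    scored: pd.DataFrame, n: int = 10, abundance_fraction: float = 0.25
) -> Metric4Selection:
    """Select the top-n peaks by |fold change| among the most abundant peaks.

    Peaks are first restricted to the top ``abundance_fraction`` (default:
    quartile) by mean normalized MALDI intensity, then the ``n`` with the
    largest absolute MALDI fold change are taken.  Ties break by abundance
    (higher first) then peak_id; fewer than n eligible peaks returns all of
    them with a warning.  Peaks with undefined fold change are ineligible.
    """
    cols = ["peak_id", "maldi_intensity_norm", "fold_change_maldi"]
    peaks = (
        scored[cols]
        .drop_duplicates(subset="peak_id")
        .dropna(subset=["fold_change_maldi"])
        .copy()
    )
    if len(peaks) == 0:
        logger.warning("metric4: no peaks with defined fold change")
        return Metric4Selection(n_requested=n, table=peaks)

    cutoff = float(peaks["maldi_intensity_norm"].quantile(1.0 - abundance_fraction))
    abundant = peaks[peaks["maldi_intensity_norm"] >= cutoff].copy()
    abundant["abs_fc"] = abundant["fold_change_maldi"].abs()
    abundant = abundant.sort_values(
        by=["abs_fc", "maldi_intensity_norm", "peak_id"],
        ascending=[False, False, True],
        kind="stable",
    )
    if len(abundant) < n:
        logger.warning(
            "metric4: only %d eligible peak(s) for a top-%d selection",
            len(abundant), n,
        )
    top = abundant.head(n).reset_index(drop=True)
    return Metric4Selection(
        peak_ids=top["peak_id"].tolist(),
        table=top,
        n_requested=n,
        abundance_cutoff=cutoff,
    )
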