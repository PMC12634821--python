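"""End-to-end orchestration: read -> normalize -> match -> filter -> score.

``run_pipeline`` executes the stages in a fixed order and maintains a count
ledger satisfying ``initial = retained + removed`` at every filter, emitted
in a machine-readable JSON run report next to the match CSV.  Stage order:

1. read the MALDI peak list and the LC-MS/MS peptide table;
2. log2-transform and per-sample-mean-normalize both, derive per-platform
   fold changes (treated minus control);
3. match every peak against all peptides within the mass tolerance and flag
   isotope duplicates;
4. knee (inflection-point) intensity cutoff, then the S/N filter;
5. estimate sigma from all surviving fold-change deltas, score with Metrics
   1-3, rank within peaks and protein groups;
6. automated top-differential (Metric 4) selection;
7. write the match CSV in the configured column order plus the JSON report.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, PepmatchError
from .matcher import flag_isotope_duplicates, match_all
from .preprocess import knee_cutoff, knee_filter, log2_normalize, snr_filter
from .scoring import estimate_sigma, metric4_top_differential, score_and_rank
from .tabular_io import (
    LcmsPeptideTable,
    MaldiPeakTable,
    RunConfig,
    read_lcms_table,
    read_maldi_csv,
    write_matches,
    write_run_report,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Scored matches plus everything the run report needs."""

    scored: pd.DataFrame
    report: dict
    retained_peak_ids: list[int] = field(default_factory=list)
    sigma: float = float("nan")
    metric4_peak_ids: list[int] = field(default_factory=list)


def run_pipeline(
    config: RunConfig,
    maldi: MaldiPeakTable | None = None,
    lcms: LcmsPeptideTable | None = None,
    write_output: bool = True,
) -> PipelineResult:
    """Run the full matching pipeline under one configuration.

    Tables may be passed in memory (synthetic runs) or read from the paths
    in ``config``.  On failure any partially written outputs are removed.
    """
    t0 = time.perf_counter()
    out_csv = Path(config.output)
    out_report = out_csv.with_suffix(".report.json")
    try:
        result = _run(config, maldi, lcms)
    except PepmatchError:
        for p in (out_csv, out_report):
            if write_output and p.exists():
                p.unlink()
        raise
    result.report["wall_time_s"] = round(time.perf_counter() - t0, 3)
    if write_output:
        write_matches(result.scored, config, out_csv)
        write_run_report(result.report, out_report)
    return result


def _run(
    config: RunConfig,
    maldi: MaldiPeakTable | None,
    lcms: LcmsPeptideTable | None,
) -> PipelineResult:
    if maldi is None:
        maldi = read_maldi_csv(config.maldi_csv, config)
    if lcms is None:
        lcms = read_lcms_table(config.lcms_csv, config)
    conditions = list(config.conditions)

    norm_maldi = log2_normalize(
        maldi.df, conditions,
        method=config.normalization, pseudocount=config.log2_pseudocount,
    )
    norm_lcms = log2_normalize(
        lcms.df, conditions,
        method=config.normalization, pseudocount=config.log2_pseudocount,
    )

    matches = match_all(maldi, lcms, config)
    matches = flag_isotope_duplicates(
        matches, config.isotope_spacing, config.isotope_window
    )
    df = matches.df.copy()
    ledger: dict[str, int] = dict(matches.ledger)

    # per-peak raw mean intensity, normalized mean intensity and fold change
    nm = norm_maldi.df
    peak_raw = nm[conditions].mean(axis=1, skipna=True)
    peak_norm = nm[[f"norm_{c}" for c in conditions]].mean(axis=1, skipna=True)
    maps = pd.DataFrame({
        "peak_id": nm["peak_id"],
        "maldi_intensity": peak_raw,
        "maldi_intensity_norm": peak_norm,
        "fold_change_maldi": nm["fold_change"],
    })
    df = df.merge(maps, on="peak_id", how="left")

    key = ["accession", "sequence", "modification_annotation"]
    nl = norm_lcms.df
    pep_fc = nl[key + ["fold_change"]].rename(
        columns={"fold_change": "fold_change_lcms"}
    )
    df = df.merge(pep_fc, on=key, how="left")
    df["delta_fold_change"] = df["fold_change_maldi"] - df["fold_change_lcms"]

    noise = knee_cutoff(peak_raw.to_numpy(dtype=float))
    if config.knee_filter:
        kept, removed = knee_filter(df, noise)
    else:
        kept, removed = df, df.iloc[0:0]
    ledger["after_knee"] = len(kept)
    ledger["removed_knee"] = len(removed)

    kept = kept.copy()
    kept["snr"] = noise.snr(kept["maldi_intensity"].to_numpy(dtype=float)) if len(kept) else np.array([])
    kept2, removed2 = snr_filter(kept, noise, config.min_snr) if len(kept) else (kept, kept)
    ledger["after_snr"] = len(kept2)
    ledger["removed_snr"] = len(removed2)
    ledger["final_matches"] = len(kept2)

    sigma = float("nan")
    if len(kept2):
        try:
            sigma = estimate_sigma(kept2["delta_fold_change"])
        except DegenerateInputError:
            sigma = 1.0
            logger.warning(
                "fewer than 2 defined fold-change deltas; sigma defaulted to 1.0"
            )
        scored = score_and_rank(kept2, sigma, config)
    else:
        scored = score_and_rank(kept2, 1.0, config)

    selection = metric4_top_differential(
        scored, n=config.metric4_top_n,
        abundance_fraction=config.abundance_fraction,
    )

    # post-filter MALDI peak set (intensity filters applied at peak level)
    peak_level = maps.copy()
    if config.knee_filter and noise.has_cutoff:
        peak_level = peak_level[
            peak_level["maldi_intensity"] >= noise.intensity_threshold
        ]
    peak_level = peak_level[
        peak_level["maldi_intensity"] / noise.noise_floor >= config.min_snr
    ]
    retained_peaks = [int(p) for p in peak_level["peak_id"]]

    report = {
        "inputs": {
            "maldi_csv": str(config.maldi_csv),
            "lcms_csv": str(config.lcms_csv),
            "maldi_rows": len(maldi.df),
            "maldi_rejected": len(maldi.rejected),
            "maldi_rejected_reasons": [list(r) for r in maldi.rejected],
            "lcms_rows": len(lcms.df),
            "lcms_rejected": len(lcms.rejected),
            "lcms_deduplicated": lcms.n_deduplicated,
            "lcms_mh_computed": lcms.n_mh_computed,
        },
        "thresholds": {
            "mass_tolerance": config.mass_tolerance,
            "round_mz_before_match": config.round_mz_before_match,
            "min_snr": config.min_snr,
            "knee_index": noise.knee_index,
            "knee_intensity_threshold": noise.intensity_threshold,
            "noise_floor": noise.noise_floor,
        },
        "normalization": {
            "method": config.normalization,
            "maldi_log2_means": norm_maldi.means,
            "lcms_log2_means": norm_lcms.means,
        },
        "sigma": None if np.isnan(sigma) else sigma,
        "seed": config.seed,
        "stages": ledger,
        "metric4": {
            "n_requested": config.metric4_top_n,
            "selected_peak_ids": [int(p) for p in selection.peak_ids],
        },
    }
    for stage_pair in (("initial_matches", "after_knee"), ("after_knee", "after_snr")):
        assert ledger[stage_pair[0]] >= ledger[stage_pair[1]]

    return PipelineResult(
        scored=scored,
        report=report,
        retained_peak_ids=retained_peaks,
        sigma=sigma,
        metric4_peak_ids=[int(p) for p in selection.peak_ids],
    )
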