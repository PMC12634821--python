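"""Mass-tolerance matching of MALDI peaks against LC-MS/MS peptides.

Every MALDI m/z is paired with ALL peptides whose theoretical [M+H]+ lies
within the tolerance (default +/-1.0 Da, boundary inclusive) — a low
resolution TOF peak can legitimately cover several peptide candidates, and
disambiguation is the scorer's job, not the matcher's.  The lookup is a
bisection over the ascending peptide-mass array (O(log n + k) per peak).

An optional integer mode rounds both sides half-away-from-zero to the
nearest integer before matching and then requires integer equality,
mirroring nominal-mass matching in the original spreadsheet workflow.

Because a peptide and its +1 Da isotope satellite can both fall inside the
window, a peptide matched by two peaks spaced ~1.00335 Da apart gets the
heavier peak's candidate flagged as an isotope duplicate — flagged, never
removed, to avoid false negatives at low resolution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError
from .tabular_io import LcmsPeptideTable, MaldiPeakTable

logger = logging.getLogger(__name__)


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (locale-independent)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def get_hits(
    query_mz: float,
    peptide_masses: np.ndarray,
    tolerance: float,
    check_sorted: bool = False,
) -> np.ndarray:
    """Indices i with ``|query_mz - peptide_masses[i]| <= tolerance``.

    ``peptide_masses`` must be sorted ascending; set ``check_sorted`` to
    verify the contract (debug use).  Returns a contiguous index array.
    """
    masses = np.asarray(peptide_masses, dtype=float)
    if tolerance <= 0:
        raise ValueError(f"tolerance must be > 0, got {tolerance}")
    if check_sorted and np.any(np.diff(masses) < 0):
        raise ContractError("peptide_masses must be sorted ascending")
    lo = int(np.searchsorted(masses, query_mz - tolerance, side="left"))
    hi = int(np.searchsorted(masses, query_mz + tolerance, side="right"))
    return np.arange(lo, hi)


@dataclass
class MatchTable:
    """All (peak, peptide) candidates plus a count ledger of every stage.

    ``df`` has one row per candidate carrying the peak's and the peptide's
    identifying fields and the signed ``delta_mass = mz - theoretical_mh``.
    ``ledger`` records counts before/after each filter so that
    ``initial = retained + removed`` holds at every stage.
    """

    df: pd.DataFrame
    tolerance: float
    rounded: bool
    ledger: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)


_CANDIDATE_COLUMNS = [
    "peak_id", "mz", "accession", "description", "gene", "sequence",
    "modification_annotation", "theoretical_mh", "delta_mass", "isotope_flag",
]


def match_all(
    maldi: MaldiPeakTable, lcms: LcmsPeptideTable, config
) -> MatchTable:
    """Emit every (MALDI peak, peptide) pair within the mass tolerance.

    In rounded mode both sides are rounded half-away-from-zero to integers
    and compared for equality.  The per-peak MALDI intensities travel with
    each candidate so later filters need no joins.
    """
    tol = config.mass_tolerance
    rounded = config.round_mz_before_match
    pep = lcms.df
    if len(pep) == 0 or len(maldi.df) == 0:
        logger.warning("match_all: empty input table, no candidates emitted")
        empty = pd.DataFrame(columns=_CANDIDATE_COLUMNS + list(maldi.conditions))
        return MatchTable(df=empty, tolerance=tol, rounded=rounded,
                          ledger={"initial_matches": 0})

    masses = pep["theoretical_mh"].to_numpy(dtype=float)
    order = np.argsort(masses, kind="stable")
    sorted_masses = masses[order]
    if rounded:
        lookup = np.array([round_half_away(m) for m in sorted_masses], dtype=float)
    else:
        lookup = sorted_masses

    rows: list[dict] = []
    for peak in maldi.df.itertuples(index=False):
        q = float(peak.mz)
        if rounded:
            hits = get_hits(float(round_half_away(q)), lookup, 0.5)
            hits = hits[lookup[hits] == round_half_away(q)]
        else:
            hits = get_hits(q, lookup, tol)
        for j in hits:
            i = order[j]
            row = {
                "peak_id": peak.peak_id,
                "mz": q,
                "accession": pep["accession"].iat[i],
                "description": pep["description"].iat[i],
                "gene": pep["gene"].iat[i],
                "sequence": pep["sequence"].iat[i],
                "modification_annotation": pep["modification_annotation"].iat[i],
                "theoretical_mh": float(masses[i]),
                "delta_mass": q - float(masses[i]),
                "isotope_flag": False,
            }
            for cond in maldi.conditions:
                row[f"maldi_{cond}"] = getattr(peak, cond)
                row[f"lcms_{cond}"] = pep[cond].iat[i]
            rows.append(row)

    df = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=_CANDIDATE_COLUMNS
        + [f"maldi_{c}" for c in maldi.conditions]
        + [f"lcms_{c}" for c in maldi.conditions]
    )
    return MatchTable(
        df=df, tolerance=tol, rounded=rounded,
        ledger={"initial_matches": len(df)},
    )


def flag_isotope_duplicates(
    match_table: MatchTable,
    isotope_spacing: float = 1.00335,
    isotope_window: float = 0.02,
) -> MatchTable:
    """Flag the heavier peak when one peptide matches two isotope-spaced peaks.

    For every peptide key matched by more than one peak, any peak pair whose
    m/z difference is ``isotope_spacing +/- isotope_window`` marks the
    heavier peak's candidate with ``isotope_flag=True``.  Nothing is
    removed; the operation is idempotent and count-preserving.
    """
    df = match_table.df
    if len(df) == 0:
        return match_table
    df = df.copy()
    key_cols = ["accession", "sequence", "modification_annotation"]
    for _, group in df.groupby(key_cols, sort=False):
        if len(group) < 2:
            continue
        mzs = group["mz"].to_numpy(dtype=float)
        idx = group.index.to_numpy()
        for a in range(len(mzs)):
            for b in range(len(mzs)):
                spacing = mzs[b] - mzs[a]
                if abs(spacing - isotope_spacing) <= isotope_window:
                    df.loc[idx[b], "isotope_flag"] = True
    n = int(df["isotope_flag"].sum())
    if n:
        logger.info("flagged %d isotope-duplicate candidate(s)", n)
    out = MatchTable(
        df=df, tolerance=match_table.tolerance, rounded=match_table.rounded,
        ledger=dict(match_table.ledger),
    )
    out.ledger["isotope_flagged"] = n
    return out
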