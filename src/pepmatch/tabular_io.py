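"""CSV and INI input/output for the peak-matching pipeline.

Inputs are plain comma-separated UTF-8 files with a header row: a MALDI peak
list (m/z plus one average-intensity column per condition/ROI) and an
LC-MS/MS peptide table (a search-engine export with accession, sequence,
modification annotation and per-condition abundances).  A single INI file
maps column names, names the two conditions, and carries every matching,
filtering and scoring constant, including the order of columns in the output
match file.

Reading is loss-reporting: every input row is either accepted or rejected
with a reason code, so the run report can always reconcile
``input = accepted + rejected``.
"""

from __future__ import annotations

import configparser
import json
import logging
import re
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, SchemaError
from .masscalc import CANONICAL_RESIDUES, peptide_mh_with_annotation

logger = logging.getLogger(__name__)

#: Every column the scored match table can emit; ordered_columns must be a
#: subset of these.
OUTPUT_COLUMNS: tuple[str, ...] = (
    "peak_id",
    "mz",
    "accession",
    "description",
    "gene",
    "sequence",
    "modification_annotation",
    "theoretical_mh",
    "delta_mass",
    "isotope_flag",
    "snr",
    "maldi_intensity",
    "maldi_intensity_norm",
    "fold_change_maldi",
    "fold_change_lcms",
    "delta_fold_change",
    "metric1",
    "metric2",
    "metric3",
    "total_score",
    "rank_within_peak",
    "rank_within_protein_group",
    "metric1_unavailable",
)


@dataclass
class RunConfig:
    """All knobs of one pipeline run, fillable from an INI file.

    Defaults mirror the published operating point: +/-1.0 Da mass tolerance,
    signal-to-noise >= 2 retention, top-10 differential selection, Gaussian
    amplitude 10 for the fold-change metric, sigmoid (scale 100, k = 10,
    x0 = 0.5) for the mass metric and sigmoid (max 5, k = 1, center 2) for
    the intensity metric.
    """

    maldi_csv: str = ""
    lcms_csv: str = ""
    output: str = "matches.csv"

    # column mapping; None -> use the condition label / canonical name itself
    maldi_mz_column: str = "mz"
    maldi_intensity_columns: dict[str, str] = field(default_factory=dict)
    lcms_accession_column: str = "accession"
    lcms_description_column: str = "description"
    lcms_gene_column: str = "gene"
    lcms_sequence_column: str = "sequence"
    lcms_modifications_column: str = "modifications"
    lcms_theoretical_mh_column: str = "theoretical_mh"
    lcms_abundance_columns: dict[str, str] = field(default_factory=dict)
    use_table_mh: bool = True  # trust an existing theoretical-m/z column

    treated: str = "Ctx"
    control: str = "Ctrl"

    mass_tolerance: float = 1.0
    round_mz_before_match: bool = False
    isotope_spacing: float = 1.00335
    isotope_window: float = 0.02
    min_snr: float = 2.0
    knee_filter: bool = True

    metric1_amplitude: float = 10.0
    metric1_center: float = 0.0
    metric2_scale: float = 100.0
    metric2_steepness: float = 10.0
    metric2_center: float = 0.5
    metric3_max: float = 5.0
    metric3_steepness: float = 1.0
    metric3_center: float = 2.0
    signed_metric2: bool = False
    metric4_top_n: int = 10
    abundance_fraction: float = 0.25  # "most abundant" = top quartile
    normalization: str = "geometric"  # or "arithmetic"
    log2_pseudocount: float = 0.0  # 0 -> zeros treated as missing

    ordered_columns: tuple[str, ...] = OUTPUT_COLUMNS
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    @property
    def conditions(self) -> tuple[str, str]:
        return (self.treated, self.control)

    def maldi_column_for(self, condition: str) -> str:
        return self.maldi_intensity_columns.get(condition, condition)

    def lcms_column_for(self, condition: str) -> str:
        return self.lcms_abundance_columns.get(condition, condition)

    def validate(self) -> None:
        if not self.mass_tolerance > 0:
            raise ConfigurationError(
                f"mass_tolerance must be > 0, got {self.mass_tolerance}"
            )
        if self.min_snr < 0:
            raise ConfigurationError(f"min_snr must be >= 0, got {self.min_snr}")
        if self.isotope_window < 0 or self.isotope_spacing <= 0:
            raise ConfigurationError("isotope spacing/window must be positive")
        if self.metric4_top_n < 1:
            raise ConfigurationError("metric4_top_n must be >= 1")
        if not 0 < self.abundance_fraction <= 1:
            raise ConfigurationError("abundance_fraction must be in (0, 1]")
        if self.normalization not in ("geometric", "arithmetic"):
            raise ConfigurationError(
                f"normalization must be 'geometric' or 'arithmetic', got "
                f"{self.normalization!r}"
            )
        numeric = (
            self.metric1_amplitude, self.metric1_center, self.metric2_scale,
            self.metric2_steepness, self.metric2_center, self.metric3_max,
            self.metric3_steepness, self.metric3_center,
        )
        if not all(np.isfinite(numeric)):
            raise ConfigurationError("scoring constants must all be finite")
        unknown = [c for c in self.ordered_columns if c not in OUTPUT_COLUMNS]
        if unknown:
            raise ConfigurationError(
                f"ordered_columns contains unknown column(s): {unknown}"
            )
        if self.treated == self.control:
            raise ConfigurationError("treated and control labels must differ")


_FLOAT_KEYS = {
    "mass_tolerance", "isotope_spacing", "isotope_window", "min_snr",
    "metric1_amplitude", "metric1_center", "metric2_scale", "metric2_steepness",
    "metric2_center", "metric3_max", "metric3_steepness", "metric3_center",
    "abundance_fraction", "log2_pseudocount",
}
_INT_KEYS = {"metric4_top_n", "seed"}
_BOOL_KEYS = {"round_mz_before_match", "knee_filter", "signed_metric2", "use_table_mh"}


def read_ini_config(path: str | Path) -> RunConfig:
    """Read an INI run configuration, filling defaults for omitted keys.

    Recognized sections: ``[files]``, ``[columns]``, ``[conditions]``,
    ``[matching]``, ``[scoring]``, ``[output]`` and ``[run]``.  A minimal
    file only needs ``[files]`` with ``maldi_csv`` and ``lcms_csv``.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    parser = configparser.ConfigParser()
    try:
        parser.read(path, encoding="utf-8")
    except configparser.Error as exc:
        raise ConfigurationError(f"cannot parse INI file {path}: {exc}") from exc

    cfg = RunConfig()
    if parser.has_section("files"):
        files = parser["files"]
        cfg.maldi_csv = files.get("maldi_csv", cfg.maldi_csv)
        cfg.lcms_csv = files.get("lcms_csv", cfg.lcms_csv)
        cfg.output = files.get("output", cfg.output)
    if not cfg.maldi_csv or not cfg.lcms_csv:
        raise ConfigurationError(
            "[files] section must name both maldi_csv and lcms_csv"
        )
    if parser.has_section("conditions"):
        cond = parser["conditions"]
        cfg.treated = cond.get("treated", cfg.treated)
        cfg.control = cond.get("control", cfg.control)
    if parser.has_section("columns"):
        cols = parser["columns"]
        simple = {
            "maldi_mz": "maldi_mz_column",
            "lcms_accession": "lcms_accession_column",
            "lcms_description": "lcms_description_column",
            "lcms_gene": "lcms_gene_column",
            "lcms_sequence": "lcms_sequence_column",
            "lcms_modifications": "lcms_modifications_column",
            "lcms_theoretical_mh": "lcms_theoretical_mh_column",
        }
        for key, attr in simple.items():
            if key in cols:
                setattr(cfg, attr, cols[key])
        if "maldi_treated" in cols:
            cfg.maldi_intensity_columns[cfg.treated] = cols["maldi_treated"]
        if "maldi_control" in cols:
            cfg.maldi_intensity_columns[cfg.control] = cols["maldi_control"]
        if "lcms_treated" in cols:
            cfg.lcms_abundance_columns[cfg.treated] = cols["lcms_treated"]
        if "lcms_control" in cols:
            cfg.lcms_abundance_columns[cfg.control] = cols["lcms_control"]

    known = {f.name for f in fields(RunConfig)}
    for section in ("matching", "scoring", "run"):
        if not parser.has_section(section):
            continue
        for key, raw in parser[section].items():
            if key not in known:
                raise ConfigurationError(f"unknown key {key!r} in [{section}]")
            try:
                if key in _FLOAT_KEYS:
                    setattr(cfg, key, float(raw))
                elif key in _INT_KEYS:
                    setattr(cfg, key, int(raw))
                elif key in _BOOL_KEYS:
                    setattr(cfg, key, parser[section].getboolean(key))
                else:
                    setattr(cfg, key, raw)
            except ValueError as exc:
                raise ConfigurationError(
                    f"[{section}] {key} = {raw!r} is not a valid value"
                ) from exc
    if parser.has_section("output") and "ordered_columns" in parser["output"]:
        cfg.ordered_columns = tuple(
            c.strip() for c in parser["output"]["ordered_columns"].split(",")
            if c.strip()
        )
    cfg.validate()
    return cfg


@dataclass
class MaldiPeakTable:
    """MALDI peak list: one row per peak, sorted ascending by m/z.

    ``df`` columns: ``peak_id`` (input row index, provenance), ``mz`` and one
    intensity column per condition label.  ``rejected`` records every dropped
    input row with its reason code.
    """

    df: pd.DataFrame
    conditions: tuple[str, ...]
    rejected: list[tuple[int, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class LcmsPeptideTable:
    """LC-MS/MS peptide identifications with theoretical [M+H]+ per row.

    ``df`` columns: accession, description, gene, sequence,
    modification_annotation, theoretical_mh, and one abundance column per
    condition label.  Rows are unique on
    (accession, sequence, modification_annotation).
    """

    df: pd.DataFrame
    conditions: tuple[str, ...]
    rejected: list[tuple[int, str]] = field(default_factory=list)
    n_deduplicated: int = 0
    n_mh_computed: int = 0
    skipped_mod_tokens: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.df)


def read_maldi_csv(path: str | Path, config: RunConfig) -> MaldiPeakTable:
    """Load a MALDI peak-list CSV, sort by m/z, reject malformed rows.

    A header-only file is a valid empty table; a non-empty file in which no
    row parses raises :class:`DataError`.
    """
    raw = pd.read_csv(path, encoding="utf-8")
    cols = [config.maldi_mz_column] + [
        config.maldi_column_for(c) for c in config.conditions
    ]
    missing = [c for c in cols if c not in raw.columns]
    if missing:
        raise SchemaError(f"MALDI CSV {path} lacks configured column(s): {missing}")

    df = raw[cols].copy()
    df.columns = ["mz", *config.conditions]
    for col in df.columns:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df.insert(0, "peak_id", np.arange(len(df)))

    rejected: list[tuple[int, str]] = []
    bad_mz = ~np.isfinite(df["mz"]) | (df["mz"] <= 0)
    for i in df.index[bad_mz]:
        rejected.append((int(df.at[i, "peak_id"]), "invalid_mz"))
    df = df[~bad_mz]
    neg = (df[list(config.conditions)] < 0).any(axis=1)
    for i in df.index[neg]:
        rejected.append((int(df.at[i, "peak_id"]), "negative_intensity"))
    df = df[~neg]

    if len(raw) > 0 and len(df) == 0:
        raise DataError(f"MALDI CSV {path}: no parseable rows out of {len(raw)}")
    if rejected:
        logger.warning("MALDI CSV %s: rejected %d row(s)", path, len(rejected))
    df = df.sort_values("mz", kind="stable").reset_index(drop=True)
    return MaldiPeakTable(df=df, conditions=config.conditions, rejected=rejected)


_FLANK = re.compile(r"^[A-Z\-\*]?\.(.+)\.[A-Z\-\*]?$")


def clean_sequence(text: str) -> str:
    """Strip flanking-residue annotation (``K.PEPTIDER.A``) and uppercase."""
    text = str(text).strip()
    m = _FLANK.match(text)
    if m:
        text = m.group(1)
    return text.upper()


def read_lcms_table(path: str | Path, config: RunConfig) -> LcmsPeptideTable:
    """Load an LC-MS/MS peptide-table CSV.

    Sequences are cleaned and uppercased; the theoretical [M+H]+ is taken
    from the table when present (and ``use_table_mh``) and computed from the
    sequence plus parsed modifications otherwise.  Duplicate
    (accession, sequence, modification) rows are collapsed with a logged
    count.
    """
    raw = pd.read_csv(path, encoding="utf-8")
    required = [config.lcms_accession_column, config.lcms_sequence_column] + [
        config.lcms_column_for(c) for c in config.conditions
    ]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise SchemaError(f"LC-MS/MS CSV {path} lacks configured column(s): {missing}")

    df = pd.DataFrame(
        {
            "accession": raw[config.lcms_accession_column].astype(str),
            "sequence": raw[config.lcms_sequence_column].map(clean_sequence),
        }
    )
    for name, col in (
        ("description", config.lcms_description_column),
        ("gene", config.lcms_gene_column),
        ("modification_annotation", config.lcms_modifications_column),
    ):
        df[name] = (
            raw[col].fillna("").astype(str) if col in raw.columns else ""
        )
    if config.use_table_mh and config.lcms_theoretical_mh_column in raw.columns:
        df["theoretical_mh"] = pd.to_numeric(
            raw[config.lcms_theoretical_mh_column], errors="coerce"
        )
    else:
        df["theoretical_mh"] = np.nan
    for cond in config.conditions:
        vals = pd.to_numeric(raw[config.lcms_column_for(cond)], errors="coerce")
        n_neg = int((vals < 0).sum())
        if n_neg:
            logger.warning(
                "LC-MS/MS CSV %s: %d negative %s abundance(s) set to missing",
                path, n_neg, cond,
            )
        df[cond] = vals.mask(vals < 0)

    rejected: list[tuple[int, str]] = []
    ok_alphabet = df["sequence"].map(
        lambda s: bool(s) and set(s) <= CANONICAL_RESIDUES
    )
    for i in df.index[~ok_alphabet]:
        rejected.append((int(i), "invalid_sequence"))
    df = df[ok_alphabet]
    if len(raw) > 0 and len(df) == 0:
        raise DataError(f"LC-MS/MS CSV {path}: no parseable rows out of {len(raw)}")

    before = len(df)
    df = df.drop_duplicates(
        subset=["accession", "sequence", "modification_annotation"], keep="first"
    ).reset_index(drop=True)
    n_dedup = before - len(df)
    if n_dedup:
        logger.info("LC-MS/MS CSV %s: collapsed %d duplicate row(s)", path, n_dedup)

    skipped: list[str] = []
    n_computed = 0
    need = ~np.isfinite(df["theoretical_mh"].to_numpy(dtype=float))
    for i in df.index[need]:
        from .masscalc import parse_modification_annotation, compute_peptide_mh

        parsed = parse_modification_annotation(
            df.at[i, "modification_annotation"], df.at[i, "sequence"]
        )
        skipped.extend(parsed.skipped_tokens)
        df.at[i, "theoretical_mh"] = compute_peptide_mh(
            df.at[i, "sequence"], parsed.modifications
        )
        n_computed += 1

    return LcmsPeptideTable(
        df=df,
        conditions=config.conditions,
        rejected=rejected,
        n_deduplicated=n_dedup,
        n_mh_computed=n_computed,
        skipped_mod_tokens=skipped,
    )


def write_matches(scored: pd.DataFrame, config: RunConfig, path: str | Path | None = None) -> Path:
    """Write the scored match table with columns exactly in configured order.

    Values round-trip exactly through ``read_matches`` (floats are written at
    full ``repr`` precision).
    """
    path = Path(path if path is not None else config.output)
    missing = [c for c in config.ordered_columns if c not in scored.columns]
    if missing and len(scored) > 0:
        raise SchemaError(f"scored table lacks output column(s): {missing}")
    out = (
        scored.reindex(columns=list(config.ordered_columns))
        if len(scored) > 0
        else pd.DataFrame(columns=list(config.ordered_columns))
    )
    out.to_csv(path, index=False)
    return path


def read_matches(path: str | Path) -> pd.DataFrame:
    """Read back a match file written by :func:`write_matches`."""
    return pd.read_csv(path, encoding="utf-8", float_precision="round_trip")


def write_run_report(report: dict, path: str | Path) -> Path:
    """Write the machine-readable JSON run report next to the match CSV."""
    path = Path(path)
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return path
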