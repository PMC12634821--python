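"""Synthetic paired MALDI / LC-MS/MS datasets with planted ground truth.

The generator emulates the inputs of the matching pipeline at realistic
statistics so every stage is testable without raw instrument data:

* **true peptides** appear in both tables — their MALDI peak sits at the
  theoretical [M+H]+ plus a Gaussian mass error (the low-resolution TOF
  side), and their condition fold changes agree across platforms up to
  platform noise (a shared latent log2 effect per peptide);
* **decoy peptides** appear only in the LC-MS/MS table, with independent
  fold changes — they compete inside tolerance windows purely by chance;
* **noise peaks** appear only in the MALDI table, at low intensity drawn
  from a separate log-normal regime, so the knee and S/N filters have
  something to remove;
* **isotope satellites** are planted 1.00335 Da above a random subset of
  true peaks at reduced intensity;
* a **trypsin control ROI** mimics the on-plate positive control: autolysis
  peptides of porcine trypsin at high, condition-balanced intensity.

Peptide sequences are tryptic-like random strings (length 7-20, C-terminal
K or R) rather than digests of a real proteome, preserving the mass
statistics without external sequence databases.  Every stochastic call is
driven by a single seeded generator; identical parameters and seed give
byte-identical tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ContractError
from .masscalc import compute_peptide_mh
from .tabular_io import LcmsPeptideTable, MaldiPeakTable

logger = logging.getLogger(__name__)

_RESIDUES = np.array(list("GASPVTCLINDQKEMHFRYW"))
ISOTOPE_SPACING = 1.00335

#: Autolysis peptides of porcine trypsin used as the on-plate control.
#: VATVSLPR has [M+H]+ 842.51 Da (nominal 843), the classic calibrant peak.
TRYPSIN_AUTOLYSIS_PEPTIDES: tuple[str, ...] = (
    "VATVSLPR",
    "LSSPATLNSR",
    "IITHPNFNGNTLDNDIMLIK",
)
TRYPSIN_ACCESSION = "TRYP_PIG"


@dataclass
class SyntheticParams:
    """Knobs of one synthetic instance; the defaults are the study
    conditions used throughout the test suite."""

    seed: int
    n_true_peptides: int = 200
    n_decoy_peptides: int = 1000
    n_noise_peaks: int = 300
    mz_range: tuple[float, float] = (700.0, 3500.0)
    mass_error_sd: float = 0.2
    isotope_satellite_prob: float = 0.1
    fold_change_sd: float = 1.5      # latent log2 effect of true peptides
    concordance_sd: float = 0.3      # per-platform fold-change noise
    signal_log2_mean: float = 13.0   # MALDI signal-peak intensity regime
    signal_log2_sd: float = 1.5
    noise_log2_mean: float = 5.0     # MALDI noise-peak intensity regime
    noise_log2_sd: float = 1.0
    lcms_log2_mean: float = 20.0     # LC-MS/MS abundance regime
    lcms_log2_sd: float = 1.5
    min_true_separation: float = 2.0  # Da between planted true masses
    max_mass_error: float = 0.99     # redraw errors beyond this magnitude
    retry_cap: int = 50
    conditions: tuple[str, str] = ("Ctx", "Ctrl")

    def __post_init__(self) -> None:
        for name in ("n_true_peptides", "n_decoy_peptides", "n_noise_peaks"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.mass_error_sd > 0:
            raise ValueError("mass_error_sd must be > 0")
        if not self.mz_range[0] < self.mz_range[1]:
            raise ValueError("mz_range must be an increasing interval")


@dataclass
class PeakLabel:
    """Ground-truth label of one generated MALDI peak."""

    kind: str  # "true" | "noise" | "isotope"
    accession: str | None = None
    sequence: str | None = None
    collision: bool = False


@dataclass
class GroundTruth:
    """Planted peak -> peptide mapping for recovery evaluation."""

    labels: dict[int, PeakLabel]
    decoy_accessions: frozenset[str]
    seed: int
    params: SyntheticParams | None = None

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "decoy_accessions": sorted(self.decoy_accessions),
            "labels": {str(k): asdict(v) for k, v in self.labels.items()},
            "params": asdict(self.params) if self.params else None,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _random_tryptic_sequence(rng: np.random.Generator) -> str:
    length = int(rng.integers(7, 21))
    body = "".join(rng.choice(_RESIDUES, size=length - 1))
    terminus = "K" if rng.random() < 0.5 else "R"
    return body + terminus


def _sample_peptides(
    rng: np.random.Generator,
    n: int,
    mz_range: tuple[float, float],
    existing_masses: list[float],
    min_separation: float,
    retry_cap: int,
) -> tuple[list[str], list[float], list[bool]]:
    """Sample tryptic-like sequences inside the m/z window, keeping each new
    mass at least ``min_separation`` from the accepted ones (retry-capped;
    an unseparable peptide is accepted with a collision flag)."""
    seqs: list[str] = []
    masses: list[float] = []
    collisions: list[bool] = []
    for _ in range(n):
        collision = True
        seq, mh = "", 0.0
        for _attempt in range(retry_cap):
            seq = _random_tryptic_sequence(rng)
            mh = compute_peptide_mh(seq)
            if not mz_range[0] <= mh <= mz_range[1]:
                continue
            if min_separation > 0 and existing_masses:
                nearest = min(abs(mh - m) for m in existing_masses)
                if nearest < min_separation:
                    continue
            collision = False
            break
        seqs.append(seq)
        masses.append(mh)
        collisions.append(collision)
        existing_masses.append(mh)
        if collision:
            logger.warning(
                "peptide %s accepted with collision label after %d retries",
                seq, retry_cap,
            )
    return seqs, masses, collisions


def generate_dataset(
    params: SyntheticParams,
) -> tuple[MaldiPeakTable, LcmsPeptideTable, GroundTruth]:
    """Generate one paired instance: MALDI peaks, peptide table, ground truth.

    True peptides receive a shared latent log2 effect (condition fold
    change) observed by both platforms with independent concordance noise;
    their MALDI mass error is redrawn while it exceeds
    ``params.max_mass_error`` so every true peak keeps its peptide inside
    the default 1 Da tolerance.  Satellites inherit the parent's intensity
    scaled down and sit one isotope spacing higher.
    """
    rng = np.random.default_rng(params.seed)
    treated, control = params.conditions

    true_masses: list[float] = []
    true_seqs, true_mhs, collisions = _sample_peptides(
        rng, params.n_true_peptides, params.mz_range, true_masses,
        params.min_true_separation, params.retry_cap,
    )
    decoy_seqs, decoy_mhs, _ = _sample_peptides(
        rng, params.n_decoy_peptides, params.mz_range, [],
        0.0, params.retry_cap,
    )

    maldi_rows: list[dict] = []
    labels: dict[int, PeakLabel] = {}
    lcms_rows: list[dict] = []

    def _next_peak_id() -> int:
        return len(maldi_rows)

    for i, (seq, mh) in enumerate(zip(true_seqs, true_mhs)):
        acc = f"TRUE{i:04d}"
        latent = rng.normal(0.0, params.fold_change_sd)
        fc_maldi = latent + rng.normal(0.0, params.concordance_sd)
        fc_lcms = latent + rng.normal(0.0, params.concordance_sd)

        err = rng.normal(0.0, params.mass_error_sd)
        while abs(err) > params.max_mass_error:
            err = rng.normal(0.0, params.mass_error_sd)

        base = rng.normal(params.signal_log2_mean, params.signal_log2_sd)
        peak_id = _next_peak_id()
        maldi_rows.append({
            "mz": mh + err,
            treated: 2.0 ** (base + fc_maldi / 2.0),
            control: 2.0 ** (base - fc_maldi / 2.0),
        })
        labels[peak_id] = PeakLabel(
            kind="true", accession=acc, sequence=seq, collision=collisions[i]
        )

        if rng.random() < params.isotope_satellite_prob:
            frac = rng.uniform(0.3, 0.7)
            sat_id = _next_peak_id()
            maldi_rows.append({
                "mz": mh + err + ISOTOPE_SPACING,
                treated: maldi_rows[peak_id][treated] * frac,
                control: maldi_rows[peak_id][control] * frac,
            })
            labels[sat_id] = PeakLabel(kind="isotope", accession=acc, sequence=seq)

        lbase = rng.normal(params.lcms_log2_mean, params.lcms_log2_sd)
        lcms_rows.append({
            "accession": acc,
            "description": f"synthetic true protein {i}",
            "gene": f"Tg{i}",
            "sequence": seq,
            "modification_annotation": "",
            "theoretical_mh": mh,
            treated: 2.0 ** (lbase + fc_lcms / 2.0),
            control: 2.0 ** (lbase - fc_lcms / 2.0),
        })

    decoy_accessions: list[str] = []
    for i, (seq, mh) in enumerate(zip(decoy_seqs, decoy_mhs)):
        acc = f"DECOY{i:04d}"
        decoy_accessions.append(acc)
        fc = rng.normal(0.0, params.fold_change_sd)
        lbase = rng.normal(params.lcms_log2_mean, params.lcms_log2_sd)
        lcms_rows.append({
            "accession": acc,
            "description": f"synthetic decoy protein {i}",
            "gene": f"Dg{i}",
            "sequence": seq,
            "modification_annotation": "",
            "theoretical_mh": mh,
            treated: 2.0 ** (lbase + fc / 2.0),
            control: 2.0 ** (lbase - fc / 2.0),
        })

    for _ in range(params.n_noise_peaks):
        peak_id = _next_peak_id()
        maldi_rows.append({
            "mz": rng.uniform(*params.mz_range),
            treated: 2.0 ** rng.normal(params.noise_log2_mean, params.noise_log2_sd),
            control: 2.0 ** rng.normal(params.noise_log2_mean, params.noise_log2_sd),
        })
        labels[peak_id] = PeakLabel(kind="noise")

    maldi_df = pd.DataFrame(maldi_rows, columns=["mz", treated, control])
    maldi_df.insert(0, "peak_id", np.arange(len(maldi_df)))
    maldi_df = maldi_df.sort_values("mz", kind="stable").reset_index(drop=True)

    lcms_df = pd.DataFrame(
        lcms_rows,
        columns=["accession", "description", "gene", "sequence",
                 "modification_annotation", "theoretical_mh", treated, control],
    )

    truth = GroundTruth(
        labels=labels,
        decoy_accessions=frozenset(decoy_accessions),
        seed=params.seed,
        params=params,
    )
    return (
        MaldiPeakTable(df=maldi_df, conditions=params.conditions),
        LcmsPeptideTable(df=lcms_df, conditions=params.conditions),
        truth,
    )


def generate_trypsin_control(
    seed: int,
    mass_error_sd: float = 0.05,
    peptides: tuple[str, ...] = TRYPSIN_AUTOLYSIS_PEPTIDES,
    conditions: tuple[str, str] = ("Ctx", "Ctrl"),
) -> tuple[MaldiPeakTable, LcmsPeptideTable, GroundTruth]:
    """Trypsin-only ROI: autolysis peptide peaks at high, balanced intensity.

    The mass error is tighter than for tissue peaks (these peaks double as
    the instrument's calibrants).  Fold changes are near zero on both
    platforms, so the control peptides score near the Metric-1 maximum.
    """
    rng = np.random.default_rng(seed)
    treated, control = conditions
    maldi_rows, lcms_rows = [], []
    labels: dict[int, PeakLabel] = {}
    for i, seq in enumerate(peptides):
        mh = compute_peptide_mh(seq)
        base = rng.normal(14.0, 0.5)
        wobble = rng.normal(0.0, 0.05)
        maldi_rows.append({
            "mz": mh + rng.normal(0.0, mass_error_sd),
            treated: 2.0 ** (base + wobble / 2.0),
            control: 2.0 ** (base - wobble / 2.0),
        })
        labels[i] = PeakLabel(kind="true", accession=TRYPSIN_ACCESSION, sequence=seq)
        lbase = rng.normal(22.0, 0.5)
        lcms_rows.append({
            "accession": TRYPSIN_ACCESSION,
            "description": "Trypsin (porcine), autolysis",
            "gene": "PRSS1",
            "sequence": seq,
            "modification_annotation": "",
            "theoretical_mh": mh,
            treated: 2.0 ** (lbase + wobble / 2.0),
            control: 2.0 ** (lbase - wobble / 2.0),
        })
    maldi_df = pd.DataFrame(maldi_rows, columns=["mz", treated, control])
    maldi_df.insert(0, "peak_id", np.arange(len(maldi_df)))
    maldi_df = maldi_df.sort_values("mz", kind="stable").reset_index(drop=True)
    lcms_df = pd.DataFrame(
        lcms_rows,
        columns=["accession", "description", "gene", "sequence",
                 "modification_annotation", "theoretical_mh", treated, control],
    )
    truth = GroundTruth(labels=labels, decoy_accessions=frozenset(), seed=seed)
    return (
        MaldiPeakTable(df=maldi_df, conditions=conditions),
        LcmsPeptideTable(df=lcms_df, conditions=conditions),
        truth,
    )


@dataclass
class RecoveryReport:
    """Recovery of planted assignments from a scored match table."""

    top1_recovery: float
    n_true_peaks: int
    n_true_with_candidates: int
    n_correct_top1: int
    decoy_top1_rate: float
    noise_survival: float | None = None
    n_noise_peaks: int = 0
    n_noise_retained: int = 0
    confusion: dict[str, int] = field(default_factory=dict)


def evaluate_recovery(
    scored: pd.DataFrame,
    truth: GroundTruth,
    retained_peak_ids=None,
) -> RecoveryReport:
    """Score a run against its ground truth.

    ``top1_recovery`` is the fraction of planted true peaks (with at least
    one surviving candidate) whose rank-1 candidate is the planted peptide.
    ``decoy_top1_rate`` is the fraction of those peaks topped by a decoy.
    When ``retained_peak_ids`` (the post-filter MALDI peak set) is given,
    ``noise_survival`` reports the fraction of planted noise peaks that
    survived the intensity filters.
    """
    known = set(truth.labels)
    seen = set(int(p) for p in scored["peak_id"].unique()) if len(scored) else set()
    if not seen <= known:
        raise ContractError(
            f"scored table contains peak ids absent from ground truth: "
            f"{sorted(seen - known)[:5]}..."
        )

    true_ids = [pid for pid, lab in truth.labels.items() if lab.kind == "true"]
    top1 = (
        scored[scored["rank_within_peak"] == 1].set_index("peak_id")
        if len(scored)
        else pd.DataFrame()
    )
    n_with, n_correct, n_decoy_top = 0, 0, 0
    for pid in true_ids:
        if len(top1) == 0 or pid not in top1.index:
            continue
        n_with += 1
        row = top1.loc[pid]
        lab = truth.labels[pid]
        if row["accession"] == lab.accession and row["sequence"] == lab.sequence:
            n_correct += 1
        elif row["accession"] in truth.decoy_accessions:
            n_decoy_top += 1

    noise_ids = [pid for pid, lab in truth.labels.items() if lab.kind == "noise"]
    survival = None
    n_retained = 0
    if retained_peak_ids is not None:
        retained = set(int(p) for p in retained_peak_ids)
        n_retained = sum(1 for pid in noise_ids if pid in retained)
        survival = n_retained / len(noise_ids) if noise_ids else 0.0

    return RecoveryReport(
        top1_recovery=n_correct / n_with if n_with else float("nan"),
        n_true_peaks=len(true_ids),
        n_true_with_candidates=n_with,
        n_correct_top1=n_correct,
        decoy_top1_rate=n_decoy_top / n_with if n_with else float("nan"),
        noise_survival=survival,
        n_noise_peaks=len(noise_ids),
        n_noise_retained=n_retained,
        confusion={
            "true_top1_correct": n_correct,
            "true_top1_decoy": n_decoy_top,
            "true_top1_other": n_with - n_correct - n_decoy_top,
        },
    )


def write_dataset(
    out_dir: str | Path,
    maldi: MaldiPeakTable,
    lcms: LcmsPeptideTable,
    truth: GroundTruth,
) -> dict[str, Path]:
    """Write the three artifacts (two CSVs + JSON ground truth) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "maldi_csv": out / "maldi.csv",
        "lcms_csv": out / "lcms.csv",
        "ground_truth": out / "ground_truth.json",
    }
    # write in generation order (peak_id), so that re-reading the CSV assigns
    # row-index peak ids that agree with the ground-truth labels
    (
        maldi.df.sort_values("peak_id", kind="stable")
        .drop(columns=["peak_id"])
        .to_csv(paths["maldi_csv"], index=False)
    )
    lcms.df.to_csv(paths["lcms_csv"], index=False)
    paths["ground_truth"].write_text(truth.to_json() + "\n", encoding="utf-8")
    return paths
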