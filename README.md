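# pepmatch

Match low-resolution MALDI imaging mass spectrometry (MALDI-MSI) peaks to
high-resolution LC-MS/MS peptide identifications, and rank the candidate
assignments.

## The problem

MALDI-MSI maps peptide ions across a tissue section but cannot, on a
TOF-class instrument, identify them: a peak at nominal m/z 946 with a ±1 Da
mass window may cover several of the thousands of peptides identified by a
parallel LC-MS/MS run on an adjacent section. `pepmatch` bridges the two
datasets. For every MALDI peak it retrieves *all* LC-MS/MS peptides whose
theoretical singly protonated mass [M+H]⁺ falls within the tolerance, filters
out noise-level peaks, and scores each candidate with three bounded metrics
so the most plausible peptide (and its parent protein) ranks first.

It is intended for spatial-proteomics practitioners running a
MALDI-TOF/TOF or timsTOF imaging platform alongside an Orbitrap LC-MS/MS
workflow, working from peak-list and search-export CSVs.

## The scoring model

Intensities on both platforms are log2-transformed and centered on the
per-sample mean, giving each peak/peptide a log2 fold change between the two
conditions (e.g. treated "Ctx" vs vehicle "Ctrl"). Candidates are scored by

- **Metric 1 — fold-change concordance** (0–10):
  `y = 10·exp(−x² / 2σ²)` where `x = fc_MALDI − fc_LC-MS/MS` and σ is the
  sample SD of all deltas in the filtered match table;
- **Metric 2 — mass agreement** (0–100):
  `y = 100 / (1 + exp(10·(|Δm| − 0.5)))` with Δm in Da — sharply penalizing
  offsets beyond ~0.1 Da;
- **Metric 3 — MALDI intensity** (0–5):
  `y = 5 / (1 + exp(−(x − 2)))` of the normalized log2 peak intensity.

The Peptide Score is the sum (≤ 115). Candidates are ranked within each
MALDI peak and within each protein group. Noise is removed before scoring by
a knee cutoff on the sorted intensity curve plus a signal-to-noise ≥ 2
filter. A fourth, automated selection step picks the top-10 most abundant
peaks with the largest fold-change differences between conditions. Peptides
matched by two peaks spaced ~1.00335 Da apart are flagged as isotope
duplicates (never removed).

A synthetic-data module generates paired tables with planted true matches,
decoy peptides, noise peaks, isotope satellites and a trypsin-autolysis
control ROI, so the whole pipeline is testable without instrument data.

## Worked example

```sh
pepmatch simulate --out demo --seed 7 --n-true 40 --n-decoy 150 --n-noise 60
printf '[files]\nmaldi_csv = demo/maldi.csv\nlcms_csv = demo/lcms.csv\noutput = demo/matches.csv\n' > demo/run.ini
pepmatch match --config demo/run.ini
# wrote 51 candidate rows to demo/matches.csv (sigma=0.9929)
```

The first rows of `demo/matches.csv`:

```
        mz sequence  delta_mass  metric1   metric2  metric3  total_score  rank_within_peak
833.460683  MHLGFTK    0.026872 9.662436 99.126187 4.944576   113.733198                 1
833.460683  HGEHVVR    0.023042 4.217649 99.158745 4.944576   108.320970                 2
833.460683  LMVDSIR    0.005742 0.386982 99.291442 4.944576   104.622999                 3
843.344855  GMLFGYR   -0.073306 9.963573 98.616933 4.624064   113.204570                 1
```

The peak at m/z 833.46 matched three peptides within ±1 Da; all have small
mass errors (high Metric 2), so the concordant fold change (Metric 1: 9.66
vs 4.22 vs 0.39) is what puts the planted true peptide MHLGFTK at rank 1.
The run report (`demo/matches.report.json`) records the stage ledger — 55
initial matches, 4 removed by the knee cutoff, 51 final — along with
σ = 0.993, thresholds, seed and the top-10 differential peak selection.

Compute theoretical masses directly:

```sh
printf 'ESLLAEQR\nVATVSLPR\n' > seqs.txt
pepmatch masses --sequences seqs.txt
# ESLLAEQR  945.5000
# VATVSLPR  842.5094
```

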