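# Methods

## Mass calculation

Theoretical peptide masses are computed by residue summation over a fixed
table of standard monoisotopic (and average) residue masses to five
decimals, with water 18.010565 Da and proton 1.007276 Da:

    [M+H]+ = Σ residue masses + water + Σ modification deltas + proton

Monoisotopic masses and charge 1 are the defaults: MALDI produces
predominantly singly charged ions, and the matching window (±1 Da) makes
sub-millidalton mass-table precision irrelevant. The built-in variable
modifications are oxidation (+15.994915 Da on M) and deamidation
(+0.984016 Da on N/Q), matching the upstream database-search settings; the
registry is extendable. Non-canonical residue letters (B, Z, X, U, O) are
rejected outright — a silently approximated theoretical mass would corrupt
the Δmass metric. When the LC-MS/MS export already carries a theoretical
m/z column it is used verbatim (`use_table_mh`), preserving fidelity to the
search engine's own calculation; otherwise masses are computed here.

## Normalization and fold changes

Intensities are log2-transformed, then centered on the per-condition mean
of log2 values (division by the geometric mean of raw values). The
published description — normalizing each log2 value "by the average
intensity per sample" — is ambiguous between geometric- and
arithmetic-mean centering; the geometric form is the default because the
downstream fold-change metric operates on log2 differences, and a config
flag (`normalization = arithmetic`) provides the other reading. Zeros and
missing cells are excluded rather than floored: a pseudo-count would
fabricate fold changes (an optional `log2_pseudocount` is available). The
platform fold change is `norm[treated] − norm[control]`, undefined when
either side is missing; candidates with an undefined delta are flagged
(`metric1_unavailable`, Metric 1 = 0), never dropped.

## Noise cutoff and S/N filter

The "inflection point of the sorted intensity curve" is operationalized as
a knee detector: intensities sorted descending, log2-transformed, both axes
rescaled to [0, 1], knee at the maximum perpendicular distance to the chord
joining the endpoints. This is deterministic and parameter-free, appropriate
for a cutoff the original description itself calls arbitrary. Degenerate
curves — fewer than three distinct values, constant, or geometric decay
(linear in log2, so the chord coincides with the curve) — yield a no-cutoff
result that filters nothing.

The noise floor is the median intensity of peaks below the knee (the
minimum positive intensity if none are), and the S/N filter keeps matches
with `intensity / noise_floor ≥ min_snr` (default 2, boundary inclusive).
The knee and S/N filters are applied sequentially, knee first; both are
meaningful only when the peak list contains a noise population — a
trypsin-control ROI containing only calibrant peaks is run with
`knee_filter = false` and `min_snr = 0`.

## Matching

For each MALDI m/z, all peptides with `|mz − [M+H]+| ≤ tolerance` are
retrieved by bisection over the ascending mass array (O(log n + k) per
peak). The boundary is inclusive and the comparison absolute in Da (no ppm
mode): the published operating point fixes ±1.0 Da for both platforms.
The optional integer mode rounds both sides half-away-from-zero and
requires integer equality. All peptides tying on mass are emitted — ranking,
not matching, disambiguates. When one peptide matches two peaks spaced
1.00335 ± 0.02 Da apart, the heavier peak's candidate is flagged as an
isotope duplicate; flagging is idempotent and removes nothing, since
deisotoping at TOF resolution risks false negatives.

## Scoring and ranking

Metrics 1–3 are as in the README; all constants (A = 10, k = 10, x₀ = 0.5,
max 5, k = 1, center 2) are config-exposed. Two points were genuinely open:

- **Metric 2 input.** The literal formula applied to a *signed* delta awards
  > 50 to any negative mass error regardless of magnitude. The default here
  scores |Δm|, since error magnitude, not sign, measures agreement;
  `signed_metric2 = true` restores the literal form.
- **Metric 3 input.** The intensity scale for the sigmoid (center 2) is not
  stated. The implementation feeds the normalized log2 mean MALDI intensity
  of the peak; since normalized values center near 0, the center (and
  steepness) remain config-exposed rather than being treated as definitive.

σ for Metric 1 is the sample SD (n − 1) of *all* defined deltas in the
post-filter match table — a single global estimate, clamped below at 1e-6.
Ranking is by total score, descending, within each MALDI peak and within
each protein group, with a deterministic tie-break: smaller |Δm|, then
higher MALDI intensity, then accession, then sequence. Both ranks are
emitted; within-protein-group ranking is often the more selective view.

Metric 4 (automated differential selection) couples abundance and
difference: peaks are first restricted to the top quartile by mean
normalized intensity ("most abundant", fraction config-exposed) and the
n = 10 with the largest |fold change| are selected, ties broken by
abundance then peak id.

## Synthetic data

The generator plants: true peptides present in both tables (MALDI m/z =
theoretical mass + N(0, 0.2 Da) error, redrawn in the rare case it exceeds
0.99 Da so the planted peptide stays inside the default tolerance); decoy
peptides only in the LC-MS/MS table; noise peaks only in the MALDI table;
isotope satellites +1.00335 Da above 10% of true peaks at 30–70% intensity.
Fold-change concordance is modeled as a shared latent log2 effect
N(0, 1.5) per true peptide observed by each platform with independent
N(0, 0.3) noise; decoy fold changes are independent N(0, 1.5). Intensity
regimes are log-normal: MALDI signal log2 ~ N(13, 1.5), MALDI noise
log2 ~ N(5, 1), LC-MS/MS abundance log2 ~ N(20, 1.5) — a ~250-fold
signal-to-noise separation typical of peak-picked average spectra.
Sequences are tryptic-like random strings (length 7–20, C-terminal K/R),
preserving mass statistics without a proteome database; a m/z window of
700–3500 Da mirrors a typical peptide-imaging acquisition range.

True peptide masses are kept ≥ 2 Da apart from each other (retry-capped,
collision-labelled) so top-1 ground truth is unambiguous; decoy masses are
unconstrained and compete inside tolerance windows by construction. The
trypsin control ROI emits porcine autolysis peptides (VATVSLPR at
842.51 Da — nominal 843 — LSSPATLNSR, IITHPNFNGNTLDNDIMLIK) with a tighter
0.05 Da mass error, these peaks being the instrument's de facto calibrants,
and near-zero fold change on both platforms.

What the generator does **not** emulate: pixel-level images and spatial
autocorrelation (only ROI-averaged intensities), correlated decoy/true
abundances, mass-dependent error or resolution, detector saturation,
chemical (structured) noise, and shared peptides across proteins. Passing
recovery tests therefore demonstrates the pipeline's behavior under the
stated statistical model, not performance on real tissue data.

## Problem sizes and determinism

The default test instance uses 200 true pairs, 1,000 decoys and 300 noise
peaks — the scale at which, under the model above, top-1 recovery sits at
~0.90 with ~1–9% noise survival depending on the seed; tests pin their
seeds. Matcher correctness is verified against an all-pairs brute-force
oracle on 50 random instances up to 1,000 peaks × 5,000 peptides, and the
mass calculator against an independent summation oracle plus pyteomics
(agreement ≤ 5e-4 Da, the rounding level of the 5-decimal residue table).
All randomness flows through one seeded generator per run; identical seed
and configuration reproduce byte-identical outputs (CSV floats are written
at full repr precision and read back with round-trip parsing).

## Known limitations

No formal FDR estimation: a top-ranked candidate always exists, so
reliability rests on the metric scores and flags, not on a decoy-calibrated
error rate. No ppm tolerance mode, no multiply charged ions, no
isotope-envelope deconvolution, and vendor raw formats (imzML, Bruker .d)
are out of scope — inputs are assumed already peak-picked and exported to
CSV.
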