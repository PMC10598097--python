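# Methods

## Scope and model

`kmdlign` analyzes centroided, externally calibrated ESI-HRMS peak lists of
lignin extracts. It assumes singly charged (de)protonated ions ([M−H]⁻ in
negative mode, [M+H]⁺ in positive mode; adducts, multimers and multiple
charging are out of scope), m/z ≈ 100–2000, and sub-ppm mass accuracy of
the kind FT-ICR instruments deliver. Profile data, centroiding, phasing
and recalibration are upstream of this package.

## Preprocessing

The default cleaning chain is

    blank subtraction → S/N filter → normalization → 1 % filter

- **Blank subtraction** removes a sample peak when a matched solvent-blank
  peak lies within `blank_tol_ppm` (default 1.0 ppm) and the blank
  intensity is at least `blank_intensity_ratio` times the sample intensity
  (default 0, i.e. an m/z match alone suffices). Removal — rather than
  intensity differencing — is the conservative interpretation of vendor
  "subtraction"; the intensity-ratio criterion is available but off by
  default. Subtraction precedes normalization so the percent scale is
  anchored on a genuine sample peak.
- **S/N filter**: the noise level is the median raw intensity of the
  lowest `noise_quantile` (default 20 %) of peaks; peaks below
  `snr_min × noise` (default 3×) are dropped. The noise level is a
  property of the acquisition, so it is estimated once per spectrum and
  cached; re-filtering reuses the cached estimate, which makes the filter
  idempotent by construction (re-estimating from an already filtered
  spectrum would inflate the estimate and cascade). Spectra with fewer
  than 5 peaks skip the filter with a warning.
- **Relative-intensity filter** drops peaks *below* 1 % of the base peak;
  a peak at exactly 1.0 % survives. Whether the original workflows applied
  this cut before or after formula finding is ambiguous; here it runs
  before, so the formula search only sees retained peaks.

All filters return subsets of their input (no peak creation) and are
idempotent; these properties are enforced by tests.

## Kendrick transform and gating

KM = m/z × nominal/exact of the repeating unit; for CH2 the factor is
14 / 14.01565006 (the package's pinned atomic masses reproduce the
conventional 14.01565 at five decimals). KMD = round-half-up(KM) − KM,
giving KMD ∈ (−0.5, 0.5]: the nearest-integer convention produces the
negative defects seen for strongly oxygenated species, and every member of
an exact CH2 ladder shares one KMD value bit-for-bit scaled. A ceiling
convention (KMD ∈ [0, 1)) is available for comparison with tools that use
it. Charge 1 is assumed throughout.

Peak groups are gated with explicit polygons in (KM, KMD) space (shapely
point-in-polygon; boundary points included, never silently dropped). A
gated area with fewer than 5 peaks is not a group — it is returned as an
explicit rejection carrying the count. Polygon files are plain CSV
(`km,kmd` vertices), making gating reproducible where interactive lasso
selection is not.

Homologous-series detection clusters points on KMD by single linkage
within `kmd_tol`, then finds maximal sets whose KM values differ pairwise
by integer multiples of the nominal base mass within 2×`kmd_tol`
(equivalently: maximal windows of KM-mod-14 residues, treated circularly).
The result is independent of input order, and is tested against an
independent maximal-clique search on the explicit pairwise-compatibility
graph.

## Formula assignment

For a neutral mass m (observed m/z ± one proton, 1.007276466 u), the
search enumerates all compositions C_c H_h N_n O_o S_s with

- element ranges C 1–90, H 4–200, N 0–5, O 1–23, S 0–1 (defaults;
  user-settable),
- |theoretical − m| ≤ 0.5 ppm (symmetric window),
- DBE = C − H/2 + N/2 + 1 in [0, 50],
- integer DBE (even-electron neutral species; configurable), and
- the valence bound H ≤ 2C + N + 2 (configurable).

Candidates are ordered by |ppm error|, then fewer heteroatoms (N+O+S),
then lexicographic element counts; a peak receives the first candidate.
The ordering extends the lowest-mass-error rule with deterministic
tie-breaks. Peaks with no in-window candidate are reported unassigned, not
errors.

Two independent routes implement the search. The production route iterates
the (S, N, O) lattice and solves the hydrogen count from the mass residual
vectorized over carbon — inside a sub-ppm window at most two H values can
fit, so the inner dimension collapses. The oracle route materializes the
full element grid (capped at 10⁷ combinations, loud error beyond) and
window-filters it. Both routes decide acceptance and ordering through one
shared canonical error computation, so agreement is exact; the test suite
and acceptance script verify set-and-order equality on hundreds of random
masses.

The default O minimum of 1 follows the study settings even though rare
oxygen-free N/S species are then unreachable; setting `o=(0, 23)` admits
them. Isotope-pattern verification is intentionally not implemented.

Pinned monoisotopic masses (u): C 12 exactly, H 1.00782503, N 14.00307401,
O 15.99491462, S 31.97207117; proton 1.007276466. The table is
cross-checked against pyteomics in the test suite but never consulted at
run time.

## Characterization

Group summaries report min/max ranges over members (KM/KMD from all
members; H/C, O/C, DBE and heteroatom classes from assigned members only)
plus the classes unique to the group within its comparison set. Solvent
rankings count post-filter peaks, whole-spectrum or inside one group's
gate; ties break alphabetically so rankings are deterministic. "Optimum 3
solvents" is the top three of the per-group ranking by count (summed
intensity is available as an alternative metric — the choice between count
and intensity is genuinely open, and count is the simpler, more robust
default for screening). Ratio trends report class means (organic/aqueous
ratio ≥ 0.5 vs < 0.5) and a Spearman rank correlation, with no
significance claim: the screening design is observational, one spectrum
per mixture.

Cross-sample group matching scores pairs by intersection-over-union of
their (KM, KMD) bounding boxes and matches greedily in descending score;
pairs under `min_overlap` (default 0.3) dissolve and leftovers are
reported unique to their side. Degenerate (zero-area) boxes match only
when identical. Box IoU with greedy matching is a deliberate simplification
of matching by eye; it is symmetric under side-swapping and is tested as
such.

## Synthetic data generator

The generator emulates the statistical structure the analysis relies on,
with full per-peak ground truth:

- **Chemistry.** Components are condensation oligomers of the H/G/S
  monolignol units (one water lost per bond) decorated with ±CH2
  (homologous series), +O, +NH and +S within the elemental limits. The
  default library has four groups of 24 formulas (three CH2 ladders of
  eight each): G-dimer series (DBE 10–11), oxygenated S-dimer series
  (DBE 10–12), a reduced high-H/C low-DBE band, and an N/S
  contaminant-class band. The cores were chosen so the four groups occupy
  disjoint KMD bands (0.088–0.134, 0.163–0.208, 0.241–0.264, 0.333–0.360)
  — CH2-ladder members share KMD exactly, so a group's band is just its
  cores' KMDs — making polygon gating cleanly decidable and letting tests
  attribute every gated point.
- **Solvent response.** Each formula of a group enters a given spectrum
  with probability logistic(slope × (ratio − midpoint)) in the mixture's
  organic/aqueous ratio. Three groups favor organic-rich mixtures
  (slopes +8…+12), one favors aqueous-rich (−10); the asymmetry gives the
  whole-spectrum peak count a recoverable upward trend in the ratio,
  mirroring the qualitative behavior of real lignin screens. The ten
  default mixtures are the standard screening set (ratios 0.25, 0.5,
  0.75).
- **Signal model.** Included formulas are emitted at theoretical ion m/z
  with Gaussian jitter of `ppm_sigma` = 0.15 ppm (comfortably inside the
  0.5 ppm window, so assignment errors are dominated by genuine ambiguity,
  not noise) and log-normal intensities (σ = 0.4 around a group's mean
  log-intensity ≈ ln 10⁶). Real intensity distributions for lignin
  components are not known; log-normal is a modeling choice. Forty
  background noise peaks (uniform m/z, intensities 100–2000, far below
  the 1 % threshold) and six fixed contaminant m/z values — emitted in
  samples and matched blanks alike — complete each spectrum.
- **Determinism.** Every operation takes a mandatory seed;
  identical seeds give bit-identical spectra and truth tables. Dataset
  simulation derives per-solvent child seeds from one root seed.

What the generator does *not* emulate: isotopologues, multiple charging,
adducts, peak-shape/resolution effects, correlated calibration drift, and
the long-tailed component-count distributions of real lignin. Passing
tests therefore demonstrate the pipeline's correctness and recoverability
under the stated model, not instrument-level performance on real extracts.

## Numerical choices

- m/z is carried at full double precision; `.xy` output uses
  shortest-round-trip formatting so I/O is lossless.
- Duplicate m/z values on ingestion are merged keeping the maximum
  intensity, with a warning (duplicates indicate centroiding artifacts).
- Relative intensities are computed as `(I / I_max) × 100` in that
  association order so the base peak is exactly 100.0.
- The two formula-search routes share one canonical error computation to
  avoid float-associativity disagreements at window boundaries.
- Benchmark problem sizes — 500 benchmark peaks, 200 oracle masses, 20
  ranking seeds, 10⁵ KMD draws — keep the full validation suite and the
  acceptance script at about a minute on one CPU while leaving every
  statistical check well-powered.

## Known limitations

- Formula assignment at high mass (> 700 u) occasionally prefers a wrong
  candidate under jitter when two compositions fall inside the window;
  the per-mass-bin recovery report exposes this.
- Blank subtraction can, with small probability, remove a genuine sample
  peak that coincides with a blank noise peak within tolerance.
- The S/N filter's cached noise estimate means a spectrum subsetted by
  other means retains the original estimate; this is intended (noise is
  an acquisition property) but differs from re-estimating per call.
- `find_series` may return overlapping series when residue windows
  overlap; callers needing a partition must post-process.
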