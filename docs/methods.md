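# Methods

This note documents the models, estimators, and design choices behind
`apnet`, in the order the pipeline runs them.

## Spectral estimation and wPLI

Recordings are segmented into non-overlapping 4-s epochs; a trailing
partial segment is discarded, and an epoch-drop hook stands in for
artifact rejection (synthetic data are clean). Each epoch is mean-removed
and tapered: a single Hanning window for delta (2–4 Hz) and theta (4–7 Hz),
and DPSS multitapers for alpha (7–13 Hz, half-bandwidth W = 1 Hz), beta
(13–30 Hz, W = 2 Hz) and gamma (30–60 Hz, W = 4 Hz). The taper count is
K = 2·T·W − 1 with NW = T·W and T = 4 s — the standard multitaper choice
when only the smoothing half-bandwidth is specified. Because the
literature on this paradigm reports beta findings both as 13–30 Hz and as
13–18 Hz without reconciling the two, a named `beta_low` preset (13–18 Hz)
ships alongside the default `beta`; neither claims primacy.

Every (epoch, taper, in-band FFT bin) triple is one cross-spectral
observation S_xyt = X_x(f)·conj(X_y(f)). The estimators are

- PLI_xy = |mean_t sgn(imag S_xyt)|,
- wPLI_xy = |Σ_t imag S_xyt| / Σ_t |imag S_xyt|,

with two conventions worth stating. First, the **0/0 case**: when the
imaginary cross-spectrum vanishes identically (identical channels, or pure
zero/π-lag coupling) wPLI is defined as 0, consistent with the estimator's
designed blindness to such coupling. Second, **pooling**: the default forms
a single ratio over all observations of a band jointly (epochs × tapers ×
bins); a per-bin-then-average variant is available via `wpli(obs,
per_bin=True)` since the original pooling convention is not recoverable.
Hanning bands pool across bins exactly like DPSS bands.

Numerically, tapered Fourier coefficients are held in complex64 and the
pairwise imaginary sums are accumulated in float64 by a compiled streaming
kernel; the ratio is invariant to positive rescaling, so single precision
in the coefficients is ample (unit tests pin the estimators to exact
rational fixtures at 1e-10).

## Graph construction and metrics

"Minimal spanning tree" thresholding is implemented as the
**maximum-wPLI** spanning tree (equivalently the minimal tree of the
distance 1 − wPLI): retaining the strongest edges is the only reading
consistent with subsequently "adding the highest remaining edges". Kruskal
with the deterministic edge order (weight descending, node-index pair
ascending) makes degenerate ties reproducible. Sweep networks are nested
by construction; the edge count at density d is ⌈d·n(n−1)/2⌉, and
densities below the MST density — e.g. the printed 0.036 on 28 nodes,
where the tree alone is ≈0.0714 — are clamped up to the MST with a
warning. The printed nine-density grid is the default; it is config-driven
because the original grid ("ten thresholding levels", nine printed values)
is not exactly recoverable.

Metrics are binary: C_i = 2t_i/(k_i(k_i−1)) with C_i = 0 for degree < 2,
global C the node mean; L_i the mean shortest-path hop count from node i,
global L the node mean (connectedness is guaranteed by the MST backbone).
On binary networks the weighted triangle formula (w^(1/3) products)
reduces to exactly this, which is why no separate weighted mode exists.
Random references are Maslov–Sneppen double edge swaps with connectedness
enforced (10·k attempted swaps, 50 surrogates by default; the generator
and counts are this package's choice, as none are prescribed). γ = C/C_rand,
λ = L/L_rand, σ = γ/λ. Complete or too-small graphs admit no swap and fall
back to the original with a warning.

## Behavioral scoring

Final frequencies are scored in cents against the octave-equivalent
equal-tempered target nearest to them, i.e. folded into [−600, +600) with
A4 = 440 Hz; the half-open interval resolves the exact-tritone tie
deterministically. MAD is the mean |deviation|; SDfoM is the sample SD
(divisor N−1) of the |deviations| around MAD — the notation for this
quantity is ambiguous between signed and absolute deviations, and the
absolute reading matches its verbal definition. Z-scores standardize
against the RP (non-AP) group. AQ scoring gives one point per item
endorsed in the keyed autistic direction, reverse-keyed items inverted;
the bundled 50-item key (5 subscales × 10 items, alternating polarity)
reproduces the instrument's structure without its copyrighted text. PIS
scoring is octave-free pitch-class equality with enharmonic spellings
equated; whether the original screen demanded octave-correct naming is
unstated, and octave-free is assumed. Group assignment is AP ⇔ > 12/36,
with explicit logged overrides for re-assigned borderline subjects.

## Group inference

Sweep cells get Welch two-sample t tests (two-sided; sidedness of the
original sweep is unstated, and two-sided is the conservative choice) with
Cohen's d (pooled SD, (n−1) weights). Multiple comparisons across the
density grid use the **two-successive-thresholds rule**: a cell survives
only if an adjacent density in the same metric × band × condition strip is
also significant at α = 0.05; a secondary mask at 0.10 mirrors the
marginal findings convention. Each surviving run's representative density
is its max-|d| cell. Cells where a metric is degenerate across all
subjects (e.g. clustering identically zero on the MST-clamped density) are
recorded with p = 1 rather than failing the sweep.

Edge-level tests permute group labels (not signs), apply the same shuffle
to all edges, and use the add-one estimator p = (#{|perm| ≥ |obs|} + 1) /
(n_perm + 1), so min p = 1/(n_perm+1); BH-FDR at q = 0.05 (level and
variant are this package's defaults, as none are prescribed). The
standardized variant z-scores each subject's matrix over its n(n−1)/2
unique off-diagonal entries first.

OLS regressions report R², adjusted R², F, and AIC in the Gaussian
−2·loglik + 2(p+1) convention (statsmodels); model rankings are invariant
to the additive constant, which is the only thing that matters for
comparison tables (AIC ascending, ties by adjusted R²). Mediation is a
percentile bootstrap over the product of coefficients a·b (a from m~x, b
from y~x+m) with case resampling; no specific mediation method is
prescribed by the study, and this is the common nonparametric choice.

## Synthetic cohorts: what they emulate and what they do not

Each channel is unit-RMS 1/f¹ noise (slope configurable) — the standard
EEG background assumption; the study does not model noise. A coupling adds
a shared narrow-band Gaussian oscillation: white noise shaped by a
Gaussian spectral bump at the band's geometric-center frequency
(bandwidth min((f_hi−f_lo)/8, 1) Hz), with the second channel's copy
phase-rotated by a constant lag on all positive frequencies. This is
equivalent to a carrier with a slow random amplitude/phase envelope, so
the imaginary cross-spectrum is single-signed for the coupled pair but
independent couplings remain independent processes — uncoupled pairs stay
at the estimator's noise floor. Zero and π lags are rejected for nonzero
strength because they are invisible to wPLI by construction.

The default cohort encodes the study conditions: 31 AP + 33 RP, 28
channels, 512 Hz, 300 s per condition, EO and EC. Both groups share
identical alpha (O1–O2) and theta (Fz–Pz) couplings; beta couplings
occupy twelve channels at strength 1.2 with identical 3-regular degree
sequences but opposite topology — three K4 cliques (RP, 12 triangles)
versus a 3-regular bipartite graph (AP, triangle-free) — so the AP group
has lower beta clustering across the density sweep while degrees and
path-length structure stay comparable. Behavioral defaults are anchored
to the published group summaries: trial noise σ = 52 cents (AP) vs 450
cents (RP), which reproduce MAD means near 41 vs ~297 cents through the
half-normal identity E|ε| = σ√(2/π) and the ±600-cent folding; AQ trait
locations −0.365/−0.674 (expected totals ≈ 20.5/16.9); starting ages
5.97 ± 2.97 vs 7.12 ± 2.22 years; PIS accuracies 0.85 vs 0.15. Normal
trial error is an assumption (the empirical single-trial distribution is
uncharacterized) and is flagged in the config.

Deliberately **not** simulated: volume-conduction mixing, artifacts
(blinks, EMG), electrode drift, and spatially correlated background noise.
Passing recovery tests therefore demonstrate that the estimators and the
inference chain do what they claim on data matching their assumptions —
not that the pipeline is robust to real-world EEG artifacts, which the
original study handled with ICA and manual rejection upstream of this
pipeline's scope.

## Problem sizes in tests and the acceptance script

The validation suite runs the full chain at the study's group sizes
(31 + 33) but with 60-s single-condition recordings and three bands
(beta plus the two uncoupled control bands), 50 replicates for the
recovery study; the acceptance script uses 10 replicates by default
(`--recovery-replicates`). Type-I calibration uses 500 null simulations
with 1,000 permutations on 10-node matrices; the pipeline default for
real analyses remains 10,000 permutations. Null-model checks average γ
and λ over eight 28-node random-graph instances with 50 surrogates each,
and evaluate Watts–Strogatz σ (n = 28, k = 4, p = 0.1) over 100 seeds with
10 surrogates per seed. These sizes are the package's own validation
choices; all are configurable.

## Known limitations

- The two-successive-thresholds rule is a heuristic, not a calibrated
  family-wise error control: metric values at adjacent densities are
  strongly autocorrelated (nested networks), so null significances arrive
  in runs even when the per-cell test is perfectly calibrated. In the
  recovery simulations each null metric × band strip produces a surviving
  run in roughly 4–8% of cohorts, which accumulates over metrics, bands,
  and conditions to a family-wise false-run rate above 10% — the
  `null_band_false_run_rate` the validation suite and acceptance script
  compute makes this visible. Findings from single strips under this rule
  should be read accordingly.
- wPLI at 60 s (15 epochs) has a noise floor around 0.1 for uncoupled
  pairs; group comparisons absorb this, but single-subject edge values at
  short durations should not be over-read.
- The density grid's lowest printed value lies below the 28-node MST
  density and is clamped; results at that density reflect the MST alone.
- `run_pipeline` simulates; analyzing a pre-existing written cohort end to
  end is done stage-by-stage through the CLI (`connect`, `graph`, `score`,
  `stats`).
- EDF files are read (via mne) but cohorts are written as delimited TSV
  matrices, the package's interchange format.
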