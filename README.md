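# apnet — resting-state EEG connectivity and graph analysis for absolute-pitch cohorts

`apnet` is a reusable pipeline for a question at the intersection of network
neuroscience and psychoacoustics: do musicians with absolute pitch (AP — the
ability to name or produce a tone without a reference) have differently
organized resting-state functional brain networks than relative-pitch (RP)
musicians, and do those differences track autistic traits and pitch
proficiency?

The pipeline covers, end to end:

1. **Connectivity.** Multichannel resting-state EEG (28 channels, 512 Hz,
   eyes-open and eyes-closed) is cut into non-overlapping 4-s epochs and
   transformed with multitapers per frequency band (Hanning for delta 2–4 Hz
   and theta 4–7 Hz; DPSS with K = 2·T·W − 1 tapers and half-bandwidths
   ±1/2/4 Hz for alpha 7–13, beta 13–30, gamma 30–60 Hz). Every
   (epoch, taper, in-band bin) yields a cross-spectral observation
   S_xyt, and connectivity per channel pair is the **weighted phase lag
   index**

   wPLI_xy = |Σ_t imag(S_xyt)| / Σ_t |imag(S_xyt)|  ∈ [0, 1],

   which weights each phase lead/lag by the magnitude of the imaginary
   cross-spectrum and is blind to zero- and π-lag coupling (volume
   conduction). The unweighted PLI is also provided.

2. **Graph metrics.** Each wPLI matrix is binarized by an MST-seeded density
   sweep: the maximum-weight spanning tree guarantees a connected backbone,
   then the strongest remaining edges are added up to each target density
   (defaults 0.036…0.291). Per network: global clustering C, characteristic
   path length L, and their ratios against degree-preserving
   double-edge-swap surrogates — γ = C/C_rand, λ = L/L_rand, and
   small-worldness σ = γ/λ.

3. **Behavior.** Pitch-adjustment trials are scored in cents against the
   nearest octave-equivalent equal-tempered target (A4 = 440 Hz):
   MAD = mean |deviation| (accuracy) and SDfoM = SD of the |deviations|
   (consistency), z-standardized against the RP group. AQ questionnaires
   (50 items, 5 subscales, reverse-keyed items) and the 36-tone PIS naming
   screen (AP ⇔ > 12 correct) complete the subject scores.

4. **Inference.** Welch-test sweeps over (metric × band × condition ×
   density) with a two-successive-thresholds significance rule and max-|d|
   representative densities; edge-wise permutation tests (10,000 label
   shuffles, BH-FDR) on raw and z-standardized matrices; OLS regressions
   with R²/AIC model comparison; percentile-bootstrap mediation.

Because the original subject-level data are not publicly deposited, the
package ships a first-class **synthetic cohort generator**: 1/f background
noise plus narrow-band phase-lagged couplings with known group topology
(the default cohort gives the AP group a triangle-free beta-band coupling
graph and the RP group clique couplings with identical degrees, i.e. a
recoverable beta clustering deficit), plus half-normal-style pitch errors,
Bernoulli AQ responses, and PIS accuracy per group.

## Worked example

```python
import numpy as np
from apnet.synthgen import CohortConfig, generate_cohort
from apnet.pipeline import (compute_connectivity, compute_metrics_table,
                            DEFAULT_DENSITIES)
from apnet.stats import sweep_group_tests

cfg = CohortConfig(duration_s=60.0, conditions=("EO",), seed=11)
cohort = generate_cohort(cfg)                      # 31 AP + 33 RP subjects
conns = compute_connectivity(cohort, ("theta", "alpha", "beta"))
groups = {s.subject_id: s.group for s in cohort.subjects}
metrics = compute_metrics_table(conns, groups, DEFAULT_DENSITIES,
                                compute_random=False)
sweep = sweep_group_tests(metrics, value_cols=("C", "L"))
surv = sweep.surviving()
print(len(surv[(surv.metric == "C") & (surv.band == "beta")]),
      "surviving beta clustering cells;",
      len(surv[surv.band != "beta"]), "in the uncoupled bands")
```

prints

```
3 surviving beta clustering cells; 0 in the uncoupled bands
```

i.e. the injected beta-band clustering difference survives the
two-successive-thresholds rule at three adjacent densities, while theta and
alpha — where both groups share identical couplings — stay quiet.

The same chain is available from the shell:

```bash
apnet simulate --seed 1 --n-ap 4 --n-rp 4 --duration 60 --out cohort/
apnet connect cohort/recordings/AP01_EO.tsv --band beta --out conn.tsv
apnet run --seed 1 --out results/run1    # full pipeline with defaults
```

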