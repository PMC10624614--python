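# slowwave

Wavelet **semblance** and **coherence** reactivity indices between slow-wave
(0.003–0.05 Hz) oscillations of cerebral optical/hemodynamic channels
(MABP, HbO2/HHb and derived HbD/HbT, oxCCO, BFI), plus the downstream
small-cohort statistics that relate those indices to MRS/histology outcome
markers. Because the original animal recordings are not public, the package
ships a first-class **synthetic cohort generator** with known coupling
structure (per-pair phase lag and coupling weight) and outcomes linearly
linked to the latent coupling, so every stage of the analysis is testable
against ground truth.

## What it does

1. **simulate** — cohorts of multichannel recordings: band-limited
   stochastic slow-wave oscillations with per-pair phase lag applied as a
   constant per-frequency phase offset (so the latent target semblance is
   exactly cos(lag)), baseline drift, broadband noise, optional Poisson
   transient artifacts, per-channel native sampling rates, and outcomes
   (BGT/WM Lac/NAA, TUNEL, aEEG) drawn from a linear link to the latent
   coupling. Severity tiers (control < moderate < severe) shift the
   coupling monotonically.
2. **preprocess** — baseline-threshold artifact detection (brief >15%
   excursions; sustained changes are kept) with linear repair for MABP;
   moving-SD despiking with cubic-spline repair for optical channels;
   discrete-wavelet denoising (4-tap Daubechies, soft universal threshold
   on above-band detail levels only, trend untouched); anti-aliased
   resampling onto a shared 1 Hz time base; HbD = HbO2 − HHb and
   HbT = HbO2 + HHb.
3. **indices** — analytic Morlet CWT (ω₀ = 6, 12 voices/octave), raw
   cross-spectrum phase cosine (semblance, −1…+1) and smoothed normalized
   cross-power (coherence, 0…1), averaged over in-band, inside-COI grid
   cells of the analysis epoch (default: 60 min starting 1 h after insult
   onset; for controls, the same offsets from recording start).
4. **stats** — log₁₀ transform of Lac/NAA ratios, D'Agostino–Pearson
   normality gate, OLS regressions of each index against each outcome,
   one-way ANOVA across insult groups (eta²), and good/poor two-group
   tests at the BGT Lac/NAA 0.39 cutoff (boundary assigned to "poor"),
   with Welch's correction applied when a Levene pre-test rejects equal
   variances. Effect sizes are variance-explained analogues (r², eta²,
   t²/(t²+df)); Benjamini–Hochberg-adjusted p values are emitted as an
   extra column for transparency but not used for gating.

## CLI

All stages read a YAML config (see `examples/study.yaml`) and communicate
through CSV artifacts:

```bash
slowwave run        --config examples/study.yaml --out scratch/study
slowwave simulate   --config examples/study.yaml --out scratch/sim
slowwave preprocess --config examples/study.yaml --data scratch/sim  --out scratch/prep
slowwave indices    --config examples/study.yaml --data scratch/prep --out scratch/idx
slowwave stats      --config examples/study.yaml \
    --indices scratch/idx/indices.csv --outcomes scratch/sim/outcomes.csv \
    --out scratch/stats
slowwave render-maps --config examples/study.yaml --data scratch/prep \
    --subject con00 --pair BFI-HbD --out scratch/maps.png
```

`run` produces per-subject recordings, the cohort index table, regression /
group-test / normality tables, `report.json`, and a `manifest.json` with
config snapshot, seed, library versions and SHA-256 digests of every
artifact. A single master seed drives all randomness through
`numpy.random.SeedSequence` spawning, so re-running a config reproduces
every file byte-for-byte. Exit codes: 0 success, 2 config error, 3 data
error, 4 compute error.

## Conventions and notable defaults

- Time is seconds from recording start (float); no wall-clock parsing.
- Input recordings are CSV/TSV with a `t_s` column plus channel columns
  from the closed vocabulary {MABP, HbO2, HHb, HbD, HbT, oxCCO, BFI, HR,
  SpO2, Temp}; unknown names are rejected. Non-numeric cells become masked
  samples (carried, not dropped).
- Epoch origin is the insult onset for insult groups and the recording
  start for controls ("at the same time" is interpreted as the same
  offsets from the start of monitoring).
- "Not consistent overall" excursions are operationalized as transients
  shorter than `max_artifact_s` (default 30 s); the baseline reference is
  the median of the baseline window.
- Cells under the cone of influence are excluded from band means;
  `valid_fraction < 0.5` marks an index as low-confidence.
- Coherence requires smoothing (scale-dependent Gaussian in time, 0.6
  decorrelation-length boxcar across scales); the unsmoothed estimator is
  identically 1 and is exposed only so tests can document that degeneracy.
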