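# audiomech

Analysis toolkit for insect auditory biomechanics with a transcriptomic
post-processing component:

- **`audiomech.synthetic`** — seeded generators for every input the pipeline
  consumes: thermally driven damped-harmonic-oscillator velocity traces
  (exact Gaussian discretization of the Langevin equation, optional
  effective-temperature energy injection and self-sustained limit-cycle
  oscillations), forced linear-sweep trials, two-state gating force-step
  experiments, sensitivity curves, and differential-expression tables with
  planted intersectional subset structure.
- **`audiomech.spectra`** — velocity amplitude spectra (1 Hz–10 kHz; Welch
  averaging for long traces) and the forced damped-harmonic-oscillator fit
  (best frequency, Q, amplitude; default 101–1000 Hz fit band), plus the
  baseline-vs-final recovery check (< 20 % change criterion).
- **`audiomech.energetics`** — total fluctuation power ⟨x²⟩ from the fitted
  model (closed-form or numeric-band), apparent mass via equipartition
  m = k_BT/(ω₀²⟨x²⟩), and active-vs-passive power gain
  ω_a²⟨x_a²⟩/ω_p²⟨x_p²⟩ − 1.
- **`audiomech.transducer`** — two-state single-population gating-compliance
  fit to force-displacement steps (±2000 nm analysis window, N·z/z
  parameterization with a degenerate-gating flag) and saturating CAP
  dose-response fits.
- **`audiomech.sweeps`** — DC removal (single-pole high-pass, τ = 0.015 s),
  trial averaging, envelope-based best-frequency extraction through the
  linear time→frequency map of 1↔1000 Hz sweeps, and displacement gain from
  three-parameter sigmoid fits to sensitivity curves (r² ≥ 0.9 floor).
- **`audiomech.de_subsets`** — intersectional classification of transcripts
  from three DE comparison tables (MvF/IvF/MvI) into four male-upregulated
  subsets at FDR < 0.05, plus exact cross-list overlaps.
- **`audiomech.stats_report`** — normality-gated test selection (Shapiro–Wilk
  → Welch t / Mann–Whitney / paired Wilcoxon) with Bonferroni correction.

## CLI

All commands operate on plain-text inputs (TSV traces with JSON sidecars,
TSV tables) and emit JSON/TSV:

```sh
audiomech simulate-trace --f0 337.52 --q 0.69 --duration 10 --seed 1 --output trace.tsv
audiomech fit-spectrum --input trace.tsv --band 101:1000 --output fit.json
audiomech apparent-mass --fit fit.json
audiomech power-gain --active active_fit.json --passive passive_fit.json
audiomech gating-fit --input steps.tsv --window 2e-6
audiomech sweep-bf --input sweep.tsv --f-start 1 --f-end 1000
audiomech displacement-gain --input sensitivities.tsv
audiomech classify-subsets --mvf mvf.tsv --ivf ivf.tsv --mvi mvi.tsv --fdr 0.05
audiomech compare --input groups.tsv --design independent --family 3
```

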