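# canisleep

Quantitative analysis of canine sleep polysomnography for paired drug
studies. Built for the within-subject design in which each dog is
recorded for two hours at 400 Hz on four EEG channels (F3, F4, Fz, Cz
referenced to Oz) under a control and a trazodone condition, with sleep
manually scored in 3-second epochs over four behavioural states:
wakefulness, drowsiness, NREM and REM.

The pipeline quantifies, per session and between conditions:

- **Sleep architecture** — percent time per state; state latencies with
  censoring at the recording duration (a dog that never reaches REM in
  a 120-min session is assigned a 120-min latency); the Lempel-Ziv
  production complexity c(S) of the 4-symbol hypnogram (lower c = more
  consolidated sleep cycles); and the first-order transition matrix
  P(next | current), compared cell-wise.
- **Relative power spectral density** — Welch spectra (800-ms Hann
  windows, 50% overlap) normalized to unit total power over [1, 50] Hz,
  compared per frequency bin (paired Wilcoxon or Mann-Whitney, p < 0.01).
- **Nonlinear dynamics** — Lempel-Ziv complexity of the median-binarized
  EEG (c·log₂n/n) and Bandt-Pompe permutation entropy (D = 4, τ = 1,
  normalized by log₂D!), on low [1, 16] Hz and high [17, 50] Hz signal
  components, with Kruskal-Wallis + Dunn across states.
- **Connectivity** — the Phase Lag Index PLI = |⟨sign Δφ(t)⟩| in five
  narrow bands (δ [2,4], θ [5,7], α [9,11], β [19,21], γ [34,36] Hz),
  with the condition difference ΔPLI = ⟨PLI_control − PLI_trazodone⟩
  thresholded against an ensemble of Ns = 100 phase-randomized
  surrogates (Th = μ_s + σ_s); and magnitude-squared coherence per
  channel pair on [1, 50] Hz.

Because recordings of this kind are not publicly deposited, the package
includes a synthetic-data generator that reproduces the study's shape
(Markov hypnograms, state-dependent spectral profiles, phase-coupled
channel pairs, artifact rates) so the entire chain is testable and
reproducible from a single seed. See `docs/methods.md` for the model
details and design choices.

## Worked example

Generate a 12-dog paired cohort (10-minute sessions, the
`trazodone-like` preset) and run the full analysis:

```sh
canisleep simulate --preset trazodone-like --seed 7 --out demo/cohort \
    --subjects 12 --duration-min 10
# wrote 24 sessions to demo/cohort

cat > demo/config.toml <<EOF
manifest_path = "demo/cohort/manifest.tsv"
output_dir = "demo/results"
seed = 7
EOF
canisleep run --config demo/config.toml
# results written to demo/results
```

`demo/results/` then holds plain TSV tables keyed by subject, condition,
state and band. Highlights from this exact run:

`architecture_tests.tsv` — the drug signature in the hypnograms. REM
time and latency differ (p = 0.031; most treated sessions never reach
REM, so their latency is censored at 10 min), hypnogram complexity drops
under trazodone (p = 0.00049), and the transition cells that move are
exactly the injected ones — drowsiness→drowsiness up, drowsiness→NREM
down (both p = 0.00049), NREM→REM down (p = 0.031):

```
      metric state  statistic  p_value  n_used   method
percent_time   rem        0.0  0.03125      12 wilcoxon
 latency_min   rem        0.0  0.03125      12 wilcoxon
hypnogram_lzc            0.0  0.000488     12 wilcoxon
```

`spectral_tests.tsv` — in NREM the treated arm shows higher relative
power in one contiguous significant band, [16.25, 50] Hz (p < 0.01 per
bin), and no bins below 13 Hz: the generator's 1.5× high-band power
effect, recovered where it was injected.

`delta_pli.tsv` — one edge exceeds its surrogate threshold, in the alpha
band, with the direction recorded:

```
state  band  edge    delta  threshold  flagged          direction
 nrem alpha Fz-Cz -0.47534   0.112942     True trazodone-increase
```

i.e. the injected alpha-band Fz–Cz coupling (|ΔPLI| = 0.48 against a
threshold of 0.11); the other 29 band × edge cells stay below threshold.

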