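# doseweight

Exposure (dose) weighting, movie-frame alignment and critical-exposure
estimation for cryo-EM movies.

## The problem

Biological specimens are destroyed by the electrons that image them.  In
cryo-EM movie mode the total exposure is split into many low-exposure
frames, so each frame samples the specimen at a different state of
radiation damage: early frames carry the most high-resolution signal but
the most beam-induced motion, late frames add low-resolution contrast
while their fine detail is gone.  Simply summing frames (or truncating
the movie at a guessed frame) wastes signal.  This package implements
the quantitative treatment of that trade-off for people who process
cryo-EM movies or study radiation damage:

* a **damage model**: the critical exposure `Ne(k)` — the accumulated
  exposure at which the spectral SNR at spatial frequency `k` (in 1/Å)
  falls to 1/e — parameterized as the power law

  `Ne(k) = a·k^b + c`,  defaults `a = 0.245`, `b = −1.665`, `c = 2.81`
  (e⁻/Å², 300 kV; multiply by 0.75 at 200 kV),

  with the optimal exposure `≈ 2.5·Ne(k)` that maximizes image SNR;
* an **exposure filter**: the SNR of a sum `Σ wᵢ Fᵢ(k)` of frames with
  amplitudes attenuated by `q(k, Nᵢ) = exp(−Nᵢ / (2 Ne(k)))` is
  maximized per resolution shell by the matched weights `wᵢ = qᵢ`,

  `F̃(k) = Σᵢ qᵢ(k) Fᵢ(k) / √(Σᵢ qᵢ(k)²)`,

  whose normalization preserves the noise variance of a single frame
  (Wiener and CTF-aware variants are included);
* **frame alignment**: iterative rigid registration of each frame
  against the leave-one-out sum of all other frames, with smoothing
  splines over the shift trajectories;
* an **estimation pipeline** that recovers `Ne(k)` from data: half-map
  FSC curves at increasing exposure → `SNR = 2·FSC/(1−FSC)` → per-shell
  linear regression of `ln SNR` vs `N` (slope `−1/Ne`), censored at the
  pure-noise FSC floor → power-law fit of the per-shell `Ne`;
* a **synthetic-movie generator** with known drift, known per-shell
  exponential damage and known noise, so every pipeline is testable
  against ground truth without external data.

## Worked example

Recover the damage law from 40 simulated half-map pairs at increasing
exposure (`examples/04_estimate_critical_exposure.py`):

```
simulated 40 half-map pairs, exposures 1.5 to 91.5 e-/A^2
fitted law: Ne(k) = 0.256 k^-1.646 + 2.790 (R^2 = 0.9982)
input law:  Ne(k) = 0.245 k^-1.665 + 2.810
per-shell Ne agreement over 22-3.8 A: RMS error 1.7% (28 shells)
```

The fitted constants match the law the generator used, and the
per-shell critical exposures agree within a few percent across the
usable band.  Aligning and filtering a simulated 32-frame, 100 e⁻/Å²
movie (`examples/02_simulate_and_align.py`, `03_exposure_filter.py`):

```
converged: True after 4 iterations
trajectory RMS error: 0.111 px (0.111 A)
exposure-filtered  sum: resolution 2.00 A (FSC 0.143 vs ground truth)
unfiltered         sum: resolution 3.30 A (FSC 0.143 vs ground truth)
model: at 3 A the plain sum keeps 18% of the filtered sum's SNR
```

The filter recovers the high-resolution signal the plain all-frame sum
buries under late, damaged frames.

## Command line

Four subcommands mirror the library:

```sh
doseweight simulate -o movie.mrcs --n-frames 130 --exposure-per-frame 0.769
doseweight align movie.mrcs -o sum.mrc --filter --exposure-per-frame 0.769
doseweight resum movie.mrcs sum_shifts.txt -o resum.mrc --frame-range 4:21
doseweight critexp fsc_dir/ -o fit --min-freq 0.045
```

`align` writes the aligned (optionally exposure-filtered) sum plus a
plain-text shifts file; `resum` recomputes sums from stored shifts;
`critexp` turns a directory of FSC CSVs (one per exposure) into a
per-shell `Ne` table and a dose-model config loadable by the filter.

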