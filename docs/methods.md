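# Methods

This note describes the statistical models, the synthetic-data generators,
the parameter defaults and the numerical choices used in `oligotrace`, along
with known limitations. Empirical performance figures quoted elsewhere are
those computed by the test suite and by `scripts/acceptance.py`; this note
makes no additional empirical claims.

## 1. Subunit counting by photobleaching steps

### Model

A membrane-protein complex with `n` subunits, each carrying a fluorescent tag
that matures (becomes fluorescent) independently with probability `p`, shows
`k ~ Binomial(n, p)` bleaching steps. Spots with `k = 0` are invisible and
never enter the data, so the observable step count follows the
detection-conditional binomial

```
P(k | n, p, visible) = C(n, k) p^k (1-p)^(n-k) / (1 - (1-p)^n),   k = 1..n.
```

Conditioning matters: ignoring it biases `p` upward because dark complexes
are silently censored. `conditional_binomial_pmf` evaluates this PMF via
`scipy.stats.binom` and is cross-checked in the tests against brute-force
enumeration of all `2^n` tag configurations.

`fit_p` maximizes the multinomial likelihood of an observed step-count table
over `p` (bounded scalar minimization on `[1e-6, 1]`) and reports a 95 %
profile-likelihood interval (likelihood drop of `chi2(1, 0.95)/2`, endpoints
by bisection). Goodness of fit is a Pearson chi-square in which cells with
expected count below 1 are pooled; the degrees of freedom are
`cells − 1 − fitted parameters`. `select_model` fits each candidate `n`
(default 1–4) and picks the smallest AIC, with `0` free parameters for the
monomer (its conditional PMF is degenerate at `k = 1`) and `1` (namely `p`)
otherwise; AIC ties go to the smaller `n`. A candidate that cannot explain
an observed count (`k > n`) is excluded outright (log-likelihood `−inf`).
`fit_mixture` additionally fits a two-component (by default monomer + dimer)
mixture by Nelder–Mead over softmax weights and logit `p`, from five
deterministic starts.

### Step detection

Traces are segmented by greedy best-first binary splitting minimising a
BIC-type cost

```
N · log(max(RSS, floor) / N) + penalty_scale · (2·n_changepoints + 1) · log N
```

with `penalty_scale = 2.0`; a split is accepted only if it lowers the cost.
The variance floor (`(1e-9 · scale)^2`) keeps the cost finite on noiseless
data. A merge pass removes steps smaller than `merge_fraction = 0.5` times
the median absolute step, which suppresses spurious tiny levels. Acceptance
screening (`accept_trace`) discards traces with no steps, more than
`k_max = 4` steps, a final level that does not return to background within
twice the residual noise, or a largest/median step ratio above 2.5 (suspected
coincident bleaching of two fluorophores).

### Generator

`simulate_spot_population` draws per-spot fluorophore counts
`Binomial(n_subunits, p_fluor)`, independent exponential bleach times, and
emits summed-ROI traces (constant background added then subtracted, optional
Gaussian or Poisson noise, optional blinking). `render_movie` renders the
same truth as an image stack using an integrated-Gaussian PSF (pixel-edge
normal CDF differences), from which `detect_immobile_spots` recovers spots
via the temporal maximum of a 5-frame running mean, Gaussian smoothing,
a median-absolute-deviation-robust threshold at 6 robust SDs,
`skimage.feature.peak_local_max`, and an immobility check (centroid excursion
≤ 1 px). The fair ground truth for a detector is the *resolvable* step count
(`resolvable_step_count`): bleaches within one frame interval merge into one
step and a fluorophore outliving the movie contributes none.

### Defaults and rationale

| parameter | default | rationale |
|---|---|---|
| `p_fluor` | 0.67 | typical GFP maturation efficiency for this class of experiment |
| `n_frames` / `frame_interval` | 200 / 0.1 s | 20 s of imaging, ≈ 5 bleach time constants, so almost all fluorophores bleach on camera |
| `bleach_mean_time` | 4.0 s | places most bleach events well inside the movie while keeping steps temporally separated |
| `unit_intensity` | 100 counts | one fluorophore's summed-ROI signal; noise settings are read against it (e.g. `noise_sd = 20` is SNR 5) |
| `roi_size` | 6 px | standard small-ROI summation window for diffraction-limited spots |
| `min_spot_separation` | 8 px | keeps 6-px ROIs from overlapping so traces are single-spot |
| `psf_sigma` | 1.2 px | diffraction-limited width at typical TIRF sampling |

These are the package's own simulation choices, selected so that the
generator exercises the analysis under realistic conditions; they are not
measurements.

## 2. Acceptor-photobleaching FRET

In a donor/acceptor pair with true efficiency `E`, the donor is quenched to
`D(1 − E)`. Bleaching the acceptor to depth `β` (fraction of acceptor
intensity removed) dequenches the donor to `D(1 − E(1 − β))` inside the
bleached region. Both post images also lose a fraction (scan loss) to the
extra scan; the factor `ρ` is measured as the donor post/pre ratio in an
unbleached control region and divides the post image. The reported apparent
efficiency is

```
E_app = 100 · (F_after/ρ − F_before) / F_before = 100 · β·E / (1 − E),
```

exact in the noiseless generator (verified on a grid of `E` and `β` in the
acceptance tests). The canonical `100 · (F_after − F_before)/F_after` form is
reported alongside. Acceptor bleach depth is computed from the acceptor
channel and gates quality (`qc_min_bleach = 0.7`, against a nominal target
depth of 0.8): at shallow depths the dequenching, and hence `E_app`,
underestimates proportionally to `β`.

## 3. Colocalization and dose response

Mander's coefficients within a cell mask,

```
M1 = Σ A_i[B_i > t_B] / Σ A_i,    M2 = Σ B_i[A_i > t_A] / Σ B_i,
```

with per-channel Otsu (`skimage.filters.threshold_otsu`), zero, or fixed
thresholds; the overlap coefficient `R` is reported as a secondary statistic.
`per_cell_ratio_analysis` pairs each cell's reporter-vs-ER-marker M1 with its
regulator/reporter mean-intensity ratio; `analyze_panel` refuses to pool
cells with different acquisition tags, since raw-intensity ratios are not
comparable across changed gain or laser settings. The dose response is fit
with `y = A·exp(−k·x) + C` by bounded least squares (`A, k ≥ 0`,
`C ∈ [0, 1]`), from five deterministic starts with rates spread over two
decades to avoid local minima; `R²` and a flat-fit flag are reported. The
panel generator places an ER-like disc and a membrane-like ring in a 64×64
frame and splits the reporter between them according to the true decay curve,
with the expression ratio set by construction. The pipeline's default dose
design is 30 cells spanning ratios 0–2 (`regulator_max = 200`,
`reporter_level = 100`); the acceptance checks also use the wider 0–4 span.

## 4. Determinism and numerics

All randomness flows from `numpy.random.default_rng(seed)`; movie pixel noise
uses a sub-seed (`SeedSequence([seed, 1])`) so the same spot population can
be rendered with independent noise. Report bundles serialize with sorted JSON
keys and fixed CSV schemas and are byte-identical across re-runs of the same
configuration, which the tests assert. Optimizations use deterministic
multistarts only.

## 5. Known limitations

- **Coincident bleaching.** Two fluorophores bleaching within one frame
  interval produce a single larger step. The step-count histogram therefore
  leans slightly toward lower counts, which biases the recovered `p` for
  higher-order oligomers downward by a small amount; the acceptance tests
  bound the effect rather than correcting it.
- **Overcount veto in model selection.** An observed count `k` strictly
  above a candidate's `n` gives that candidate zero likelihood, so a single
  spurious overcount (possible at low SNR) excludes the true model. At low
  SNR, screen traces with `AcceptanceParams(k_max=...)` matched to the
  largest plausible stoichiometry and inspect the counts table before
  trusting the selection.
- **Monomer/dimer mixtures are confounded with a pure dimer.** A mixture of
  monomers and dimers can reproduce a pure dimer's step-count table at a
  different `p`; `fit_mixture` warns about this. Step counting alone cannot
  break the degeneracy without external knowledge of `p`.
- **Generator realism.** Blinking is a simple additive blip model, the
  background is spatially constant, drift is linear, and the PSF is an
  isotropic Gaussian. The generators are designed to exercise the analyses
  under controlled truth, not to emulate a specific microscope.
- **Decay-fit precision at realistic noise.** With ~30 cells and per-cell
  colocalization noise of a few percent, the information content of an
  exponential dose-response design bounds how tightly `A`, `k` and `C` can be
  recovered; confidence in the rate in particular is limited. Interpret
  single-panel rate estimates with care and prefer pooling panels.
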