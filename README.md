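# oligotrace

Quantitative fluorescence analyses for membrane-protein oligomerization
studies, with a fully synthetic, truth-tagged data generator for every
analysis. The package re-implements three workflows end to end:

1. **Single-molecule photobleaching-step counting.** Immobile spots in a
   TIRF-style movie are detected, their background-corrected intensity traces
   extracted, and the number of discrete bleaching steps per trace counted by
   binary segmentation with a BIC-type penalty. The step-count histogram is
   then fit with a *detection-conditional binomial* model: for an `n`-mer in
   which each subunit carries a fluorescent tag that matures with probability
   `p`, the probability of observing `k` steps given the spot is visible at
   all is `C(n,k) p^k (1-p)^(n-k) / (1 - (1-p)^n)`. AIC-based model selection
   over candidate stoichiometries recovers `n`, and a profile likelihood gives
   a confidence interval for `p`. A hallmark of a dimer with `p ≈ 0.67` is
   near-equal one-step and two-step frequencies (≈ 0.496 / 0.504).
2. **Acceptor-photobleaching FRET.** Donor images before and after acceptor
   bleaching yield the apparent efficiency
   `E_app = 100 · (F_after_corr − F_before) / F_before`, where the after
   image is corrected for scan-to-scan loss measured in an unbleached control
   region. Incomplete acceptor bleaching scales the dequenching, so the
   measured bleach depth (nominally ~0.8) is reported and used as a quality
   gate.
3. **Mander's colocalization and dose response.** Two-channel Mander's
   coefficients (M1/M2) inside a cell mask with Otsu, zero or fixed
   thresholds, a per-cell expression ratio, and a bounded exponential-decay
   fit `y = A·exp(−k·x) + C` of colocalization versus relative regulator
   expression across a cell panel.

Every generator records ground truth (per-spot fluorophore counts and bleach
times, true FRET efficiency and bleach depth, true decay parameters), so every
estimator in the package is validated against known truth.

## Worked example

Simulate 1000 visible spots of a dimer whose tags mature with probability
0.67, count bleaching steps, and recover the stoichiometry:

```python
from oligotrace.synthetic import SimConfig, simulate_traces
from oligotrace.steps import fit_steps, accept_trace, count_distribution
from oligotrace.stoichiometry import select_model

cfg = SimConfig(seed=42, n_subunits=2, p_fluor=0.67, noise_sd=10.0)
truth, traces = simulate_traces(cfg, n_visible=1000)
table = count_distribution([accept_trace(fit_steps(t)) for t in traces])
print("step counts:", dict(sorted(table.counts.items())))
sel = select_model(table)
best = sel.fits[sel.selected_n]
print(f"selected n = {sel.selected_n} (margin {sel.selection_margin:.1f} AIC units)")
print(f"p_hat = {best.model.p:.3f}, 95% CI ({best.p_ci[0]:.3f}, {best.p_ci[1]:.3f})")
```

Output:

```
step counts: {1: 483, 2: 504}
selected n = 2 (margin 216.4 AIC units)
p_hat = 0.676, 95% CI (0.648, 0.703)
```

The near 50/50 split of one- and two-step traces is the dimer signature; the
maturation probability is recovered within its confidence interval.

The same workflows are available from the command line:

```sh
oligotrace simulate-traces --seed 1 --n-subunits 2 --p-fluor 0.67 --out traces.csv
oligotrace count-steps --traces traces.csv --out table.csv
oligotrace fit-stoichiometry --table table.csv --out report.json
oligotrace fret --seed 3 --out fret_report/
oligotrace coloc --out coloc_report/
```

and as end-to-end pipelines (`oligotrace.pipeline`) that write deterministic,
byte-reproducible report bundles (JSON results + CSV tables + provenance).

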