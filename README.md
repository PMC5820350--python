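# escapewatch

Engineered production strains lose productivity during scale-up: cells
that mutate away from the productive state ("escape") outgrow their
burdened siblings, and over the ~60–80 generations needed to fill an
industrial fermenter the population can shift almost entirely to
non-producers — while looking healthy at lab scale.  `escapewatch` is a
Python toolkit for quantifying this process, written for metabolic
engineers and fermentation scientists.  It combines:

* **A two-state population model** (`escapewatch.popmodel`): producers P
  and non-producers N with
  `dP/dg = (μ − c − k)P`, `dN/dg = μN + kP`, where `c` is the production
  load (relative fitness cost of production) and `k` the escape rate
  (per-generation conversion to the non-producing state).  Closed forms
  for the producer fraction `f = 1/(1 + ρ)` with
  `ρ(g) = (k/(c+k))(e^{(c+k)g} − 1)` and the half-life
  `g½ = ln(1 + (c+k)/k)/(c+k)`.
* **A stochastic (Gillespie) counterpart** (`escapewatch.stochastic`) for
  small populations and discrete escape events, with a hybrid
  SSA → deterministic handoff for large-scale extrapolation.
* **Nonlinear estimation of (c, k)** from stability time series — relative
  titers or mobile-element fractions — with CI95
  (`escapewatch.fitting`).
* **A population-level deep-sequencing pipeline**
  (`escapewatch.isscan`): broken-read breakpoint detection, IS-junction
  assignment via target-site-duplication signatures (3–12 bp), 80-bp
  junction-probe quantification, mobile-element coverage fractions, and
  binomial low-frequency SNP calling (1% significance, 0.25% frequency
  floor, 3-read minimum).
* **Growth-rate estimation** from microplate OD series (rolling 5-point
  log-OD regression, 0.04–0.4 band) and the production load as relative
  rate difference (`escapewatch.growth`).
* **Synthetic-data generators** (`escapewatch.synth`) that emulate the
  study design end to end — 2 × 150 bp paired reads at 7200× over a ~7 kb
  plasmid, escape spectra whose mode frequencies follow the model, OD
  plates — with ground-truth ledgers, so every stage is testable without
  external data.

## Worked example

```python
import numpy as np
from escapewatch import ModelParams, half_life, producer_fraction, fit_stability
from escapewatch.synth import simulate_stability_series

params = ModelParams(load=0.30, escape_rate=2.1e-7)
print(round(half_life(params), 1))            # 47.2
print(round(half_life(ModelParams(0.22, 2.1e-7)), 1))  # 63.0

p = ModelParams(0.30, 1e-7)
print(round(100 * (1 - producer_fraction(p, 60.0)), 1))  # 95.6
print(round(100 * (1 - producer_fraction(p, 37.0)), 1))  # 2.2

series = simulate_stability_series(ModelParams(0.281, 2.1e-7),
                                   np.linspace(14, 80, 10), noise_sd=0.0)
fit = fit_stability(series)
print(fit.estimates)
# {'load': 0.28099999..., 'escape_rate': 2.0999999...e-07}
```

Read as: a strain with a 30% production load and an escape rate of
2.1 × 10⁻⁷/generation keeps half its producers for only ~47 generations;
cutting the load to 22% stretches that to 63.  At escape rate
10⁻⁷/generation the same strain is ~96% non-producers after 60 generations
(a ~2 m³ reactor) yet shows only ~2% non-producers at 37 generations —
lab-scale performance does not predict tank-scale genetics.  The fit
recovers the generating parameters of a noiseless synthetic series to
machine precision.

The sequencing pipeline runs the same way from synthetic reads:

```python
from escapewatch import synth
from escapewatch.isscan.scan import scan_insertions

ref = synth.make_reference(seed=7)
cat = synth.make_catalog(seed=11)
spec = synth.default_spectrum(ref, cat)
reads, truth = synth.simulate_reads(ref, {"intact": 0.9, "IS10@1200": 0.1},
                                    cat, spec, depth=1500, seed=5)
freqs, events, unassigned = scan_insertions(reads, ref, cat)
print(events[0])       # InsertionEvent(position=1200, subgroup='IS10',
                       #   orientation='+', tsd_length=3, support=(...))
print(round(freqs[0].frequency, 3))   # ~0.10
```

## Analysis drivers

Numbered scripts under `analysis/` re-run the main analyses and write
tables to `results/`:

| script | what it does |
|---|---|
| `01_model_predictions.py` | half-lives, takeover percentages, fraction curves |
| `02_fit_stability.py` | fit round trips on synthetic stability series |
| `03_stochastic_consistency.py` | SSA ensemble vs deterministic fraction |
| `04_sequencing_roundtrip.py` | reads → insertions → frequencies → enrichment slopes |
| `05_growth_load.py` | plate OD → growth rates → production load |

A `escapewatch` command-line interface exposes the same stages
(`escapewatch model predict`, `simulate ssa`, `fit`, `synth reads|series|od`,
`scan-insertions`, `me-fraction`, `call-variants`, `timecourse`, `growth`,
`run`); see `escapewatch --help`.

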