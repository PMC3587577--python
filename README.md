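# quenchkit

Quantitative analysis of reversible fluorescence quenching of
dye–bipyridine–DNA probes by transition-metal ions — for spectroscopists
characterizing switchable fluorescent metal-ion probes in bulk titrations
and single-molecule blinking experiments.

A fluorescent probe **L** (a dye conjugated next to a bipyridine chelator
on a short DNA duplex) binds a metal ion **M** to form a 1:1 complex
**ML** whose emission is reduced to a fraction *f*<sub>PQ</sub> of the
free probe's. The quenching ratio then deviates negatively from the
linear Stern–Volmer law and saturates:

```
F0/F = (1 + K·c) / (1 + f·K·c)          (dilute-probe two-state model)
F0/F = 1 / (1 − (1 − f)·x),  x = [ML]/[L]0   (exact mass-balance form)
```

with association constant *K* (reported as log₁₀ *K* in M⁻¹) and quencher
concentration *c*. The package implements, end to end:

* **`quenchkit.equilibria`** — the Stern–Volmer, approximate and exact
  two-state model curves, plus a numerically stable 1:1 binding solver.
* **`quenchkit.ensemble`** — relative quantum yields from
  fluorescence-vs-absorbance slopes, quench-curve assembly with error
  propagation, and statsmodels-style `SternVolmerModel` /
  `TwoStateQuenchModel` fits returning results objects with standard
  errors, reduced χ² and `summary()`.
* **`quenchkit.benesi`** — Benesi–Hildebrand analysis of absorbance
  titrations (*K* = slope/intercept of the transformed plot).
* **`quenchkit.traces`** — single-molecule blinking traces: intensity
  histogram accumulation, three-Gaussian decomposition
  (background / dim / bright), and the background-corrected dim/bright
  brightness ratio *f*<sub>PQ,sm</sub> aggregated over molecules.
* **`quenchkit.forster`** — spectral overlap integrals
  *J* = ∫ F̄_D(λ) ε_A(λ) λ⁴ dλ and Förster radii
  R₀ = 0.02108·(κ² n⁻⁴ Φ_D J)^(1/6) nm.
* **`quenchkit.simulate`** — synthetic-data generators for every input
  (titrations, absorbance series, two-state Markov blinking traces with
  Poisson counting and single-step photobleaching, Gaussian-band
  spectra), so each stage is verifiable by parameter recovery.
* **`quenchkit.cli` / `quenchkit.io`** — the `quenchkit` command with
  subcommands `simulate`, `fit-ensemble`, `fit-bh`, `analyze-traces`,
  `forster`, `report`, and the CSV/JSON readers and writers.

## Worked example

Simulate a Cu²⁺ titration of a TMR-labelled probe (truth
log K = 6.95, f = 0.05; 21 concentrations 0–20 µM, three probe
concentrations per point, 2% photometric noise) and fit both models:

```sh
quenchkit simulate --scenario ensemble --seed 7 --out sim
quenchkit fit-ensemble --input sim/titration.csv --model compare --out fit
cat fit/report.txt
```

```
approx_two_state   logK =   6.9733 +/- 0.0147   f = 0.0525 +/- 0.0005   chi2_red = 2.004
stern_volmer       logK =   6.0682 +/- 0.0028   f =    nan +/-    nan   chi2_red = 196.2
```

The two-state fit recovers the ground truth within a few standard
errors, while the Stern–Volmer line misses the saturating curvature by
two orders of magnitude in reduced χ² — the quantitative version of the
visibly curved Stern–Volmer plot that signals static complex formation
with a residually emissive quenched state. The same fit from Python:

```python
from quenchkit import TwoStateQuenchModel, build_quench_curve, io

curve = build_quench_curve(io.read_titration_csv("sim/titration.csv"))
print(TwoStateQuenchModel(curve).fit().summary())
```

```
Quenching-model fit: approx_two_state
============================================
n points              21
reduced chi2          2.004
logK            6.9733  +/-    0.0147
f             0.052507  +/-  0.000511
```

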