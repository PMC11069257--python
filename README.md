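# affinichrom

Quantitative analysis of drug–receptor binding by affinity chromatography.

When a receptor is immobilized on a chromatographic support, a ligand's
retention and peak shape encode its binding thermodynamics and kinetics.
This package implements the three quantitative readouts used to
characterize ligand binding to an immobilized G-protein-coupled receptor
(the M3 muscarinic receptor system is the motivating application) and to
screen complex mixtures such as herbal extracts for receptor antagonists:

1. **Nonlinear chromatography (Thomas/Wade peak model).**  The elution
   profile of an overloaded injection, in reduced coordinates
   (x = t/t₀, y = Y/C₀), is

   y(x) = (a₀/a₃)·[1 − e^(−a₃/a₂)] ·
   √(a₁/x)·I₁(2√(a₁x)/a₂)·e^(−(x+a₁)/a₂) /
   (1 − T(a₁/a₂, x/a₂)·[1 − e^(−a₃/a₂)])

   with T(u,v) = e^(−v)∫₀ᵘ e^(−t) I₀(2√(vt)) dt the switching function
   and I₀, I₁ modified Bessel functions.  Fitting a baseline-corrected
   peak yields (a₀…a₃) = (area, center, width, distortion), from which

   K_A = a₃/C₀  (L/mol),  k_d = 1/(a₂t₀)  (s⁻¹),  k_a = k_d·K_A.

2. **Injection-amount-dependent (zonal) analysis.**  Retention falls as
   sites saturate; the data linearize as
   k′n_b/(1+k′) = n_t − (1/K_A)·k′V_m, so an OLS line gives K_A (−1/slope)
   and the binding-site amount n_t (intercept).  One line means one class
   of sites; two segments (adjudicated by `split_regimes`) mean two.

3. **Two-column retention-shift screening.**  Comparing void-referenced
   retention (t_R/t₀) between a conformation-constrained ("two-point")
   receptor column and a conventional ("single-point") one labels each
   ligand antagonist-like (retention enhanced), agonist-like (reduced) or
   non-binder (co-elutes with the void marker on both).

A ground-truth-known synthetic-data module generates overloaded peak
series, zonal retention series and screening mixtures, so every stage is
testable without instrument data.

## Worked example

```python
import numpy as np
from affinichrom import (SyntheticTruth, generate_peak_series,
                         fit_peak_series, series_consistency)

truth = SyntheticTruth(K_A=1.28e4, k_d=63.0, k_prime=4.26,
                       concentrations=(2.5e-4, 1.0e-3, 3.0e-3),
                       noise_sd=0.01, seed=7)
chroms, manifest = generate_peak_series(truth)
ctxs = [truth.context(c) for c in truth.concentrations]
fits = fit_peak_series(chroms, ctxs)
for conc, res in fits:
    bc = res.binding_constants
    print(f"c={conc*1e3:4.2f} mM  K_A={bc.K_A:9.3g} L/mol  "
          f"k_d={bc.k_d:6.3g} 1/s  k_a={bc.k_a:8.3g} 1/(s*M)")
print(series_consistency(fits).summary())
```

prints

```
c=0.25 mM  K_A= 1.28e+04 L/mol  k_d=  62.7 1/s  k_a=8.03e+05 1/(s*M)
c=1.00 mM  K_A= 1.28e+04 L/mol  k_d=  62.7 1/s  k_a=8.03e+05 1/(s*M)
c=3.00 mM  K_A= 1.28e+04 L/mol  k_d=  62.9 1/s  k_a=8.05e+05 1/(s*M)
series consistency (CONSISTENT at CV <= 20%): CV[K_A]=0.1%  CV[a1]=0.0%  CV[a2]=0.2%
```

i.e. from three noisy overloaded peaks the fit recovers the association
constant that generated them (truth 1.28×10⁴ L/mol) to well under 1%, the
desorption rate (truth 63 s⁻¹) to ~0.5%, and confirms that the distortion
grows with the injected amount while the center and width parameters stay
put — the model-consistency signature of a single binding site.

A command-line interface wraps the same workflows:

```bash
affinichrom simulate --k-a 1.28e4 --k-d 63 --k-prime 4.26 \
    --concentrations 2.5e-4,1e-3,3e-3 --outdir runs/
affinichrom fit-nlc --t0 1.9 --chromatograms runs/peak_c0.00025.csv,... \
    --concentrations 2.5e-4,1e-3,3e-3
affinichrom fit-zonal --t0 1.9 --breakpoint auto --records records.csv
affinichrom screen --t0 1.9 --two-point retention.csv --single-point retention.csv
affinichrom qc --series stability.csv
```

## Layout

- `affinichrom.chromatograms` — trace container, CSV I/O, baseline
  removal, apex detection, capacity factors
- `affinichrom.thomas` — switching function and peak profile, simulation
- `affinichrom.fitting` — `ThomasPeakModel` / `ThomasPeakResults`,
  binding constants, series consistency
- `affinichrom.zonal` — `ZonalBindingModel`, saturation-line fits,
  regime splitting
- `affinichrom.screening` — two-column classification, candidate
  collection, stability RSDs
- `affinichrom.synthetic` — ground-truth generators
- `affinichrom.pipeline` / `affinichrom.cli` — config-validated
  workflows and the `affinichrom` command

See `docs/methods.md` for the model assumptions, parameter conventions
and numerical design.
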