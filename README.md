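# threetau

Fast-field-cycling (FFC) NMR relaxometry measures the longitudinal
relaxation rate R1 of tissue water as a function of Larmor frequency
f ≈ 0.01–10 MHz.  Healthy and tumorous tissue separate cleanly at low
field, and fitting a physical relaxation model to the dispersion
profile R1(f) turns that contrast into numbers with biological meaning.
`threetau` implements that analysis end to end for murine
tumour-fraction studies:

* the **3-Tau relaxation model** — six parameters: surface-water time
  constant τℓ, desorption time τd, bulk-water time τb, surface-to-volume
  ratio x = Sδ/V, surface proton density Nℓ and paramagnetic-ion density
  Nσ — combining proton–proton (HH) and ion–proton (HM) dipolar
  contributions,

      R1(f) = x·R1_σℓ + (1−x)·R1_σb + x·(R1_ℓℓ + R1_ℓb) + (1−x)·(R1_bb + R1_bℓ)

* the **pre-fit exclusion rules** for the two standard instrument
  artifacts (protocol-switch discontinuity beyond 8 MHz, ¹H–¹⁴N
  quadrupolar peak near 2 MHz);
* a **multi-start grid + trust-region fitter** with a stabilised
  inversion for the weakly identified parameter directions;
* the **common-gradient biomarker screen**: for each quantity y the
  parallel model y = αᵢ + βc + ε and coincident model y = α + βc + ε
  (c = tumour fraction in %, i = cell-culture supplier) are compared by
  a nested F-test, and the quantity is classified from the gradient
  p-value and adjusted R²;
* a **synthetic cohort generator** (3 supplier groups of 11/11/10
  samples, tumour fractions 0–83%, published parameter trends, 3%
  multiplicative noise plus both instrument artifacts) standing in for
  the in vivo datasets, with full truth tables for recovery scoring.

It is written for researchers analysing FFC-NMR/NMRD dispersion data
who want a tested, reproducible reimplementation of this screening
pipeline.

## Worked example

Run the study pipeline as numbered analysis steps (or equivalently
`threetau run-all`):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_fit_profiles.py
python analysis/03_biomarker_screen.py
python analysis/04_lowfield_decomposition.py
```

Step 02 fits all 32 simulated profiles and reports recovery against the
generator truth:

```
fitted 32 profiles; median rss = 0.0144
  tau_l_us   median |relative error| =  14.4%
  tau_d_us   median |relative error| =   3.9%
  tau_b_ps   median |relative error| =   5.5%
  x          median |relative error| =   8.9%
  N_l        median |relative error| =   5.2%
  N_sigma    median |relative error| =  12.1%
```

Step 03 prints the biomarker screen (the study-summary table):

```
 quantity      units      model   gradient   p_value  adjusted_R2  percent_change_0_100       classification
 tau_l_us         us coincident -7.523e-05   0.01799       0.1452                -9.515        none-suitable
 tau_d_us         us coincident -0.0003226 1.623e-05       0.4493                -23.05 significant-but-weak
 tau_b_ps         ps   parallel    -0.1805 1.728e-10       0.7922                -43.83            biomarker
        x              parallel -3.451e-05 3.432e-05        0.672                -26.34            biomarker
      N_l spins/nm^3 coincident  -0.001369    0.3871    -0.007469               -0.6585        none-suitable
  N_sigma spins/nm^3 coincident  0.0001049    0.3974    -0.008558                0.3867        none-suitable
R1_001MHz        1/s   parallel    -0.1183 2.199e-09       0.7831                 -40.8            biomarker

biomarkers: tau_b_ps, x, R1_001MHz
```

Reading the table: the bulk-water time constant τb falls by ~44% across
the full tumour-fraction range with a highly significant common gradient
and ~79% of its variance explained — water in tumorous tissue is more
mobile, consistent with net water ingress into tumour cells.  The
surface-to-volume ratio x falls in step (cells swell), and the low-field
rate R1(0.01 MHz) — dominated by surface-layer proton pairs — declines
by ~41% over 0–100%, making it directly usable as a biomarker.  The two
spin densities show no significant trend, as expected if tumour
progression changes water content and geometry rather than composition.
Step 04 decomposes the fitted low-field rate: the surface–surface (ℓℓ)
proton-pair term carries ≈56% of R1(0.01 MHz) on average.

The same stages are scriptable from the shell:

```bash
threetau --seed 1 --out results run-all       # simulate + filter + fit + screen
threetau --out results analyze results/fits.csv   # re-run the stats stage alone
threetau print-config                          # dump all defaults as YAML
```

Real measurements can be analysed by pointing `threetau fit` /
`run-all` at a profile CSV with columns `sample_id, group,
tumour_fraction_percent, frequency_MHz, R1_per_s`.

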