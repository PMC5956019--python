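# mstkit

Affinity analysis for microscale thermophoresis (MST) and equilibrium
dialysis, built for antibody–hapten binding panels such as anti-opioid
vaccine sera, where the analytes are small drugs, the tracer is a
fluorophore-labeled hapten, and affinities span sub-nM to µM.

MST reads binding out of a fluorescence time trace: a capillary is heated
by an IR laser and the tracer's thermophoretic depletion differs between
its free and antibody-bound states. The readout per capillary is the
normalized fluorescence

```
F_norm = F_h / F_c × 1000   (‰)
```

with `F_c` the mean pre-laser ("cold") fluorescence and `F_h` the mean in a
window late in the laser-on ("hot") phase. `mstkit` covers the full tandem
pipeline:

* **Trace processing** — cold/hot window means, automated hot-window
  selection, capillary QC (baseline outliers, photobleaching, exclusion of
  the highest titrant point), fraction-bound conversion.
* **Conventional MST** — titrate antibody sites `A` against fixed tracer
  `T`; fit `F_norm(A) = U + (B−U)·f(A)` where `f` is the depletion-exact
  bound fraction

  ```
  f = ((A + T + K_d) − sqrt((A + T + K_d)² − 4AT)) / (2T)
  ```

  so sub-nM tracer is never assumed non-depleting.
* **Heterologous competition MST** — titrate an unlabeled competitor `L`
  against a fixed tracer:antibody mix; fit a log-logistic displacement
  curve for the IC₅₀, then convert to the competitor's `K_i` through the
  exact ternary one-site/two-ligand equilibrium (solved by monotone
  root-finding on the free-site concentration), the same inputs a
  practitioner feeds a K_i calculator: `K_d, I₀, T₀, L₀, IC₅₀`.
* **Equilibrium dialysis** — two-chamber (100/300 µL) partition model with
  antibody confined to the sample chamber; binding-site concentration from
  Müller's equation `[Ab_t] = b[T_t] + b·K_d/(1−b)` and `K_d` from a
  homologous competition series.
* **Degradation kinetics** — % analyte remaining, one-phase decay
  `Y = (Y₀−P)e^(−kt) + P` with half-life as a 99% CI range, and the
  first-order / non-first-order verdict used to demonstrate
  antibody-mediated protection of heroin from serum esterases.
* **Exact mass** — monoisotopic [M+H]⁺ from a molecular formula, to verify
  a synthesized tracer's HRMS identity.
* **Synthetic data** — seeded generators for every input (MST traces for
  both modes, degradation courses with and without protection, dialysis
  measurements), emulating the serial-dilution designs so each stage is
  verifiable by parameter recovery.

All concentrations are nM internally; "antibody concentration" always
means binding-site concentration (two sites per IgG).

## Worked example

`examples/` holds one short script per capability. Running
`python examples/heterologous_ki.py`:

```
true K_i   : 1.6 nM
fitted IC50: 10.80 nM  (r^2 = 0.9747)
derived K_i: 1.67 nM
```

The IC₅₀ (10.8 nM) is much larger than the K_i (1.6 nM) because at 10 nM
binding sites the competitor is itself depleted by binding and the tracer
(K_d 7.65 nM) must be displaced; the ternary conversion removes both design
effects. `examples/conventional_kd.py` prints the triplicate-style
saturation fit (`fitted K_d : 10.21 +/- 3.05 nM` against a 7.65 nM truth,
15 points used after top-point QC), `examples/equilibrium_dialysis.py` the
Müller site estimate and dialysis K_d, `examples/degradation_kinetics.py`
the first-order vs protected verdicts, and `examples/exact_mass.py` the
tracer mass check (1137.4136).

A thin CLI mirrors the workflows:

```
mstkit simulate --mode saturation --config design.yaml --seed 1 --out run.csv
mstkit fit-kd run.csv --tracer-nm 0.25 --exclude-top-point --out report/
mstkit ki --kd-nm 4.58 --i0-nm 10 --t0-nm 0.25 --l0-nm 4000 --ic50-nm 50
mstkit mass C58H69N6O12S3 --protonated-composition
```

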