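# Methods

## Binding models

**Binary (conventional MST).** One class of antibody binding sites at
total concentration `A` (nM) binds tracer at total `T` with dissociation
constant `K_d`. The bound tracer fraction is the physical root of the
mass-action quadratic, evaluated as `2A / (s + sqrt(s² − 4AT))` with
`s = A + T + K_d` to avoid cancellation when `A ≪ K_d`. The saturation
curve is fitted on the F_norm scale, `F(A) = U + (B − U)·f(A)`, with free
plateaus `U` (unbound) and `B` (bound); fitting on the F_norm or
fraction-bound scale is equivalent under this affine model.

**Ternary (competition MST).** Tracer `T` and unlabeled competitor `L`
compete for one site class `I`. With `r` the free-site concentration,
`bound_T = T₀·r/(r + K_d)` and `bound_L = L₀·r/(r + K_i)`, and the site
balance `r + bound_T + bound_L = I₀` is strictly increasing in `r`, so the
physical equilibrium is the unique bracketed root on `[0, I₀]` (Brent's
method, relative tolerance 1e-14). This is algebraically the textbook
cubic, but the root-finding form is unconditionally stable across the
>8 decades of `K_d/K_i` met in opioid panels. The IC₅₀ is defined on the
*total* competitor axis as the point where bound tracer is half its
zero-competitor value (the infinite-competitor plateau is zero); since
bound tracer is strictly decreasing in `L`, both the forward map
`K_i → IC₅₀` and its inverse are monotone 1-D root-finding problems. The
inverse is solved on log `K_i` over [1e-6, 1e9] nM. An IC₅₀ above the
highest titrated concentration `L₀` is rejected as unidentifiable; an IC₅₀
below the design's zero-affinity floor (with sites at 10 nM, even an
infinitely tight binder has a finite IC₅₀ because the competitor is
consumed stoichiometrically) has no `K_i` and is reported as such.

**Müller's equation.** `[Ab_t] = b[T_t] + b·K_d/(1 − b)` is the exact
algebraic inverse of the binary isotherm and is used verbatim for the
binding-site concentration from the zero-competitor dialysis cell; site
estimates from different tracers are arithmetically averaged.

**Equilibrium dialysis.** Sample chamber `V_s = 100 µL` (antibody +
tracer), buffer chamber `V_b = 300 µL` (competitor). Small molecules
equilibrate to a uniform free concentration; bound ligand stays in the
sample chamber. Given free sites `r`, each ligand's free concentration has
a closed form from its mass balance, and the site balance is again
monotone in `r`. The volume asymmetry is modelled explicitly (it sets the
free-concentration baseline: 5 nM tracer in 100 µL partitions to 1.25 nM
free with no antibody). K_d estimation is homologous by construction — the
tracer is the deuterated competitor, one constant governs both — by least
squares of the forward model on the measured bound fractions, on log K_d.

## Fitting and uncertainty

All fits are unweighted trust-region least squares (`scipy`'s `trf`) with
multi-starts on a log grid of the scale parameter (K_d starts at
0.01–1000 nM, IC₅₀ starts spanning the titrated range), since affinities in
one panel span more than four decades. Confidence intervals are asymptotic
(linearized) from the Jacobian at the optimum with a t critical value —
the convention of standard nonlinear-regression software; K_i intervals
are obtained by pushing the IC₅₀ interval endpoints through the monotone
conversion. r² is `1 − SS_res/SS_tot`.

The competition curve is a log-logistic displacement
`F(L) = B + (U − B)·L^s/(L^s + IC₅₀^s)`. The Hill slope `s` is **free by
default**. The displacement is mechanistically 1:1, but on the total-L
axis antibody depletion of the competitor steepens and skews the curve
whenever `I₀` is not negligible (here 10 nM sites against nM-range K_i);
with `s` pinned at 1 the fitted midpoint is biased by >10% even on
noiseless model data, while freeing `s` brings the noiseless
generator→fitter→converter round trip within 0.3% for K_i ≥ 1 nM. The
residual case is a competitor much tighter than the site capacity
(K_i ≈ 0.4 nM under this design), where the curve approaches a
stoichiometric titration and any symmetric sigmoid underestimates the
midpoint by a few percent, which the steep IC₅₀→K_i sensitivity near the
floor amplifies to ≈15–20% on K_i; this is a documented limit of the
two-step IC₅₀ procedure, not of the ternary model (a direct ternary fit
avoids it but is deliberately not the default, to mirror the two-step
field practice).

One-phase decay `Y(t) = (Y₀ − P)e^(−kt) + P` is fitted with the plateau
fixed at 0 by default (complete hydrolysis); the half-life `ln 2/k` is
reported with a 99% CI from the rate's asymptotic interval through the
monotone transform. A course is classified **non-first-order** when the
fitted r² falls below 0.95 or the course does not decay at all. The
threshold is necessarily approximate — observed first-order courses show
r² ≥ 0.975 while rejected ones run ≈0.35–0.97 — so it is a configurable
parameter with the default in the gap.

## Trace model and QC

The synthetic trace is phenomenological: cold plateau, exponential
approach to the hot plateau after laser-on (time constant interpolating
between 1.0 s free and 1.5 s bound), back-diffusion after laser-off, slow
photobleaching (2×10⁻⁴ fraction/s), and multiplicative Gaussian count
noise (CV 0.5% per sample at 4 Hz). The analysis consumes only window
means — cold `[laser_on − 4 s, laser_on − 0.5 s]`, hot
`[laser_off − 1.5 s, laser_off]` by default, laser on at 5 s and off at
35 s — so Soret-level physics would add nothing testable. The bound state
lowers F_norm by 50‰ by default (sign configurable). Automated hot-window
selection scans 1-s windows from laser_on + 1 s and scores each by
response amplitude over the residual SD of a preliminary hyperbolic fit
(a small residual floor keeps the score amplitude-dominated on noiseless
data); ties go to the earliest window, making selection deterministic.

QC flags, all annotations that never alter values: baseline outliers
(cold mean off the series median by >10%), bleaching (pre-laser slope
beyond 1%/s of the cold mean), and on request the highest titrant point
(the abrupt buffer-composition change at the top of a serial dilution can
distort the signal; the serum saturation analysis drops its 50 nM top
point and fits the remaining 15). Both tolerances are configurable because
no instrument-recommended values are published. Noisy fraction-bound
values are not clipped to [0, 1] before fitting (clipping biases least
squares).

## Dilution arithmetic

A titration design is specified by its working-stock concentration: the
1:1 serial dilution itself halves the stock into the first tube, and the
equal-volume mix with the tracer (or tracer:antibody) solution halves
again, so final in-capillary concentrations are
`top_working × mix_ratio / dilution_factor^j`, j = 1..16. A 16,000 nM
working competitor therefore tops out at 4,000 nM final, a 6,400 nM
working antibody at 1,600 nM final, and a 100,000 nM working competitor
(the extended naloxone-style range) at 25,000 nM final.

## Degradation model

Esterases hydrolyse only free heroin; binding is fast relative to
hydrolysis, so the course integrates
`d[H_total]/dt = −k_free·[H_free]([H_total])` with the free concentration
from the binary rapid-equilibrium solution against the antibody sites
(LSODA, rtol 1e-10). With no antibody this reduces exactly to first-order
decay. The protected regime (heroin ≤ sites) reproduces the observed
phenomenology — little degradation over hours, and a non-first-order
verdict once measurement noise dominates the tiny residual trend — but the
ODE is this package's own construction; no mechanistic enzymology
(Michaelis–Menten, inhibitor dose–response) is modelled, and reproducing
full protection at equimolar heroin requires an effective in-serum K_d
tighter than the nominal solution-phase affinity.

## Exact mass

Monoisotopic masses come from the NIST table (via pyteomics). Two adduct
conventions exist in print: a neutral formula plus a proton (1.007276 Da),
and a formula that already contains the adduct hydrogen, whose reported
m/z is then the plain monoisotopic atom sum (the electron mass, 0.55 mDa,
neglected). Both are supported; the Cy5-hapten tracer's printed
composition follows the second convention (plain sum 1137.4136; the
electron-corrected ion mass would be 1137.4130).

## Synthetic data: what it does and does not emulate

Generators are pure functions of (parameters, seed). Defaults encode the
study designs: 16-point 1:1 dilutions; 0.25–1.0 nM tracer; 50 nM (serum)
or 1600 nM (monoclonal) top final sites; 10 nM sites / 0.25 nM tracer for
competition; 100/300 µL dialysis with 5 nM tracer and an 8-level
competitor series bracketing the transition; degradation sampled at
0–3 h with 5% measurement CV, the half-life truth set mid-range of the
published 0.305–0.545 h interval (0.42 h). Not emulated: capillary optical
variation beyond the QC scenarios, adsorption/nonspecific binding in
dialysis (the zero-site week-0 control is emulated as exactly zero sites),
chromatographic quantification error structure, and serum matrix effects.
Parameter-recovery results therefore demonstrate estimator correctness and
precision under the stated noise model, not robustness to every artifact
of real instruments. Under the defaults the serum saturation design
(top-point excluded, so the bound plateau is extrapolated) yields
replicate scatter somewhat wider than published triplicate SDs.

## Reproduction studies

The acceptance script and the headline tests rerun each published design
with the published affinity as ground truth: 100 seeded replicates per
MST/ED target (34 per tracer level for the three-concentration monoclonal
study, pooled), median reported. These sizes hold the full battery to
about half a minute on one CPU while leaving the median's Monte-Carlo
error well inside the reported uncertainties.
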