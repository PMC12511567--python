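# Methods

## Membrane compositions and SFA content

A lipid species is annotated with its acyl chains as (carbons, double
bonds) pairs; a chain is saturated iff it has zero double bonds.
Glycerophospholipids carry exactly two chains, sterols none. The SFA
content of a mixture is

    SFA% = 100 · Σᵢ mol%ᵢ · sᵢ / Σᵢ mol%ᵢ · cᵢ

over non-sterol species i with sᵢ saturated of cᵢ total chains.
Cholesterol is excluded from numerator and denominator, which makes the
value invariant both to common rescaling of all mol% and to diluting the
phospholipids with sterol. Compositions must sum to 100 mol% within a
tolerance (default ±0.5) that accommodates entries rounded to one
decimal (e.g. 66.7/16.7/6.7/10, sum 100.1).

The built-in table holds the eleven study mixtures. Two conventions to
be aware of:

* The "+cholesterol" mixtures keep the label of their parent
  phospholipid mix as metadata; their recomputed chain arithmetic is
  ~37% and ~59%, not the 35/60 in the label.
* The "35% SFA" mix is recorded as POPC 70 / DOPC 10 / DOPE 20, the
  only PC/PE split at the 80:20 PC:PE ratio consistent with its label
  (noted in the data file header).

Unknown abbreviations are rejected rather than guessed; callers supply
explicit chain annotations for species outside the built-in library.

## Assay formulas

**Generalized polarization.** GP = (Ip1 − Ip2)/(Ip1 + Ip2) with band
sums over samples whose wavelength lies inside the closed intervals
402–460 nm (p1) and 470–530 nm (p2). Band bounds are treated as
inclusive on both ends — the convention at the 460/470 nm boundary is a
genuine choice, made once and documented here. Sums are raw sample
sums, appropriate for a fixed instrument wavelength step; a trapezoidal
mode exists for unevenly sampled spectra but is not the default.

**FRET ratio.** Acceptor/donor intensity ratio (default I614/I516) read
at the nearest recorded wavelength, not interpolated: plate readers
report discrete steps (2 nm here) and nearest-sample lookup keeps the
quantity an observable rather than a model value.

**Lane fractions.** Modified fraction = selected band intensity / total
lane intensity. Image segmentation is out of scope; the module consumes
already-quantified band intensities.

## Two-state loading kinetics

### Model and assumptions

States: active A, inactive (membrane-associated) B, ubiquitin-loaded C.
A⇌B with rates k₁ (A→B) and k₂ (B→A); loading A→C at k₃ (pseudo-first
order in the E1·ubiquitin machinery, assumed constant). The reaction
starts from the pre-equilibrated mixture B₀/A₀ = k₁/k₂ with
A₀ + B₀ = T and C(0) = 0; T is the loadable fraction (T = 0.75 in the
global fit, absorbing material that never loads). Discharge of C is
neglected on the loading timescale — it is minute-scale and
lipid-insensitive — and appears only in the cycling model below.

### Solution

The (A, B) subsystem is linear with matrix
[[−(k₁+k₃), k₂], [k₁, −k₂]]; its eigenvalues

    r₁,₂ = [−(k₁+k₂+k₃) ± √((k₁+k₂+k₃)² − 4k₂k₃)] / 2

are real (the discriminant is ≥ (k₂−k₃)²) and non-positive. With
A(t) = c₁e^{r₁t} + c₂e^{r₂t} fixed by A(0) and A′(0), the loaded
fraction is C(t) = k₃·[c₁φ(r₁,t) + c₂φ(r₂,t)], φ(r,t) = (e^{rt}−1)/r,
and B = T − A − C by conservation. This construction — rather than a
transcribed biexponential formula — is used deliberately: it provably
satisfies C(0) = 0, reduces to T(1−e^{−k₃t}) when k₁ = 0, and tends to
T as t → ∞, and it is cross-validated against stiff numerical
integration (LSODA, rtol 1e-10) to 1e-8 across random parameter sweeps.
A published closed form for this model that fails the k₁ = 0 and t → ∞
checks should be presumed a typographical variant of this solution.

Numerical details: φ uses `expm1` (accurate for |rt| ≪ 1) with the
r = 0 limit t; degenerate eigenvalues (|r₁−r₂| < 1e-10·|r₁+r₂|) switch
to the confluent branch A(t) = (A₀ + ct)e^{rt} with
∫t·e^{rt} = (t·e^{rt} − φ)/r. Outputs are clipped to [0, T] to absorb
last-ulp excursions.

### Global fitting

Unweighted least squares on loaded fractions, replicates entered as
individual residuals (no weighting scheme is assumed; optional 1/σ
weights are accepted). k₃ is shared across conditions, k₁ and k₂ are
per-condition, T is fixed. Rates are optimized as logarithms (bounds
1e-6–1e4 s⁻¹) with scipy's trust-region-reflective least squares,
restarted from 16 deterministic initializations (one heuristic start —
k₃ near the inverse of the earliest sample time — plus seeded
log-uniform draws); the best final cost wins. Standard errors come from
the Jacobian at the optimum (covariance of log-rates via pinv(JᵀJ)·s²,
delta method back to rates); they are linearized estimates, not
profile likelihoods. Preconditions: at least two conditions, each with
four or more time points spanning a decade — below that the three-rate
model is not identifiable.

Quenched-flow and manual time courses are merged by keeping manual
records only inside a closed window (default 30–600 s), the regime
manual sampling can resolve; provenance is kept in a `source` column.

### Steady-state cycling

With continuous E1 supply, loaded E2 discharges and reloads. Adding
C→A at rate k_d to the cycle gives the stationary loaded fraction

    C/(A+B+C) = (k₃/k_d) / (1 + k₁/k₂ + k₃/k_d),

equal to 1 when k_d = 0 (absorbing loaded state). The ratio of loaded
fractions between two conditions differing in k₁/k₂ tends to 1 as
k_d → 0 and to (1+q_high)/(1+q_low) as k_d → ∞: the conformational
equilibrium influences throughput only when loading/discharge cycles
are frequent. This three-state cycle is this package's minimal model
of that regime — a deliberately simple stand-in validated against
numerical integration of the cycle, not a fitted mechanism; its
numbers should not be quoted as experimental results.

## Poisson-mixture contact analysis

Per-frame contact counts n between the UBC domain (residues 1–168,
1-based) and the membrane are modeled as P(n) = Σₖ πₖ Poisson(n; λₖ).
EM with closed-form M-step (λₖ = responsibility-weighted mean, πₖ =
mean responsibility) runs on the compressed (unique value, frequency)
representation, so cost scales with the count range, not the number of
frames. Means are initialized at K data quantiles (log-normally
jittered across restarts, sd 0.4; uniform weights); 20 restarts by
default; convergence when the relative log-likelihood gain falls below
1e-10; component means floored at 1e-6 so the zero-peak "unbound"
component stays a proper Poisson rather than a structural zero (a
zero-inflated variant was considered and rejected as an extra parameter
the count histograms do not demand). Components are reported sorted by
mean; weights below 1e-6 set a `degenerate` flag.

Model selection minimizes BIC = −2·logL + (2K−1)·ln n over K = 1..K_max
(default 6); Ks whose 10·K-observation requirement fails are dropped
with a warning.

Bound-state population is a sum of component weights under a mandatory,
reported policy: `threshold` (mean > 15 contacts ⇒ bound; counts the
tightly bound states, threshold midway between the loosely bound ~8 and
bound ~30 components) or `all_but_unbound` (everything except the
smallest-mean component). The two policies answer different questions
and can differ by the loosely-bound weight (~0.10 under the default
generator), which is why neither is reported without its name.

Per-residue contact frequency is the mean over frames of the contact
indicator (any nonzero entry of a frames × residues matrix).
Trajectory processing (distance cutoffs, bead selections) is out of
scope; the module consumes precomputed counts.

## Synthetic data generators

The generators emulate the statistical structure of the real
observables, with all randomness derived from an explicit seed:

* **Loading curves.** C(t) from the kinetic model plus iid Gaussian
  noise (sd 0.02), clipped to [0, 1], on 20 log-spaced times from 5 ms
  to 600 s (quenched-flow through manual sampling). Default conditions
  share k₃ = 30 s⁻¹ and differ in conformational rates — "60% SFA":
  k₁ = 0.005, k₂ = 0.02 s⁻¹ (≈80% fast pool); "10% SFA": k₁ = 0.2,
  k₂ = 0.02 s⁻¹ (fast pool nearly absent). These are synthetic
  magnitudes consistent with a fast pool loading within tens of
  milliseconds and a slow pool on the minute scale; they are not
  fitted experimental values.
* **Contact counts.** Four components with means 0.2/8/30/50 and
  weights 0.40/0.10/0.35/0.15; iid mode draws the component per frame,
  Markov mode draws a hidden chain with stationary distribution equal
  to the weights (transition P = (1−a)I + a·1πᵀ, a = 1/mean_dwell,
  state-k dwell ≈ mean_dwell/(1−πₖ) frames) to emulate reversible
  membrane association. The mixture means follow the reported contact
  analysis; the weights are round numbers chosen for the generator.
* **Spectra.** Sums of Gaussian bands on a 400–600 nm, 2 nm grid plus
  optional noise, floored at zero.

What the generators do **not** emulate — and hence what passing
recovery tests do not certify about real data: correlated residuals and
baseline drift in gel quantification, clipping-induced bias near 0/1,
reconstitution-to-reconstitution variability (real replicates are
independent reconstitutions, not iid noise), non-Poisson overdispersion
of contact counts within a bound state, and photobleaching or scatter
in spectra.

## Problem sizes and tolerances in the test suite

Recovery tests use 50 000-frame contact series for the headline
four-component fit (10 000 frames across 20 seeded replicates for the
median-error property), and 9–15 seeded loading datasets of 2
conditions × 20 times × 10 replicates for fit recovery; these sizes
give comfortable margins for the asserted tolerances (±5% mixture
means, <10% shared k₃, <15% median rate error) while keeping the suite
fast. The closed-form/ODE agreement is asserted at 1e-8 absolute over
100 random parameter draws spanning rates from 10⁻²·⁵ to 10²·⁵ s⁻¹.

## Known limitations

* Rates are per-condition free parameters; nothing links them to
  membrane physical properties (no packing→rate model).
* The standard errors of the global fit assume iid Gaussian residuals.
* The cycling model treats E1 and discharge as first-order and ignores
  E3-bound intermediates.
* The EM fit pools frames; replicate trajectories are not modeled
  hierarchically.
* GP band-edge convention (inclusive at 460/470 nm) can shift GP by a
  sample's worth of intensity on coarse grids.
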