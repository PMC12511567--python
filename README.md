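# lipidsense

Analysis toolkit for how membrane lipid composition regulates the ERAD
ubiquitination cascade through the membrane-anchored E2 enzyme UBE2J2.
Written for biochemists and computational biologists who quantify
reconstituted ubiquitination assays, C-Laurdan / FRET spectroscopy and
coarse-grained membrane-protein simulations.

## What it computes

**Liposome SFA content.** Each experimental membrane condition is
labelled by the percentage of its phospholipid acyl chains with zero
double bonds: `100 · Σ(mol% · saturated chains) / Σ(mol% · total
chains)`, sterols excluded. The eleven study mixtures (ER-like, 10–60%
SFA, ±cholesterol variants) ship as built-ins.

**Two-state loading kinetics.** UBE2J2 interconverts between an active
conformation A and an inactive, membrane-associated conformation B
(rates k₁, k₂); only A is loaded with ubiquitin by E1 at rate k₃:

    dA/dt = −k₃A − k₁A + k₂B,   dB/dt = k₁A − k₂B,   dC/dt = k₃A,

starting from the conformational equilibrium B₀/A₀ = k₁/k₂ with
A₀ + B₀ = T (the loadable fraction, fixed at 0.75 in the global fit)
and C(0) = 0. The (A, B) subsystem has eigenvalue rates
r₁,₂ = [−(k₁+k₂+k₃) ± √((k₁+k₂+k₃)² − 4k₂k₃)]/2 and C(t) = k₃∫A dt,
evaluated in closed form and verified against stiff ODE integration.
A global fit shares k₃ across membrane conditions while k₁, k₂ are free
per condition. A steady-state cycling model (discharge C→A at rate k_d)
gives the loaded fraction (k₃/k_d)/(1 + k₁/k₂ + k₃/k_d), showing that
the conformational equilibrium matters most when cycling is fast.

**Contact-distribution mixtures.** Per-frame contact counts between the
UBC domain (residues 1–168) and the membrane are modeled as a
K-component Poisson mixture P(n) = Σ πₖ Poisson(n; λₖ), fitted by EM
with restarts; K is chosen by BIC and bound-state populations are sums
of component weights under an explicit policy.

**Assay formulas.** C-Laurdan generalized polarization
GP = (Ip1 − Ip2)/(Ip1 + Ip2) (bands 402–460 / 470–530 nm), FRET
acceptor/donor ratio (I614/I516), and modified-band gel-lane fractions.

**Synthetic data.** Seeded generators for loading time courses, contact
series (iid or Markov-switching) and two-band emission spectra drive the
parameter-recovery test suite and the `make-fixtures` command.

## Worked example

Simulate a two-condition loading experiment (fast-loading pool in
tightly packed membranes, slow pool in loosely packed ones) and fit the
two-state model globally:

```sh
$ lipidsense simulate-loading --out tc.csv --seed 1 --replicates 5
$ lipidsense fit-loading tc.csv --out-prefix fit
{"k3": 28.919823361666005, "rss": 0.06445452718164894, "report": "fit.json"}
$ cat fit_summary.txt
Two-state loading model, global fit
  shared k3 = 28.9198 s^-1  (SE 0.688)
  T fixed   = 0.75
  60% SFA: k1 = 0.00480872 s^-1, k2 = 0.0196587 s^-1
  10% SFA: k1 = 0.190284 s^-1, k2 = 0.0193882 s^-1
  RSS = 0.0644545 over 200 points
  converged: True
```

The data were generated with k₃ = 30 s⁻¹ shared between conditions;
the fit recovers it within ~4% at this noise level (σ = 0.02), along
with the per-condition conformational rates (generated with
k₁ = 0.005/0.2 s⁻¹ and k₂ = 0.02 s⁻¹): the "60% SFA" condition has
k₁ ≪ k₂ (mostly active, ~80% loaded within tens of milliseconds), the
"10% SFA" condition the reverse.

Fit the contact-count mixture and classify bound states:

```sh
$ lipidsense simulate-contacts --out counts.csv --seed 1
$ lipidsense fit-mixture counts.csv --out mix.json
{"K": 4, "means": [0.195, 8.034, 29.982, 49.890], "bound_fraction": 0.4998, "policy": "threshold"}
```

BIC selects four components — unbound (λ≈0.2), loosely bound (λ≈8) and
two tightly bound conformations (λ≈30 and ≈50 contacts) — and the
default policy (λ > 15) counts half the frames as tightly bound.

Membrane bookkeeping and the cycling model are one-liners:

```sh
$ lipidsense sfa "50% SFA"
50.0
$ lipidsense steady-state --k1 0.2 --k2 0.02 --k3 30 --kd 0.01
0.996347
```

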