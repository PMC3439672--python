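# Methods

## The models

Exocytic membrane fusion is driven by assembly of the SNARE four-helix
bundle (the SNAREpin) and regulated by Sec1/Munc18 (SM) proteins. The
package represents each exocytic system as a small mass-action reaction
network over explicit protein moieties:

| label | reaction | role |
|---|---|---|
| R1 | Syx + S25 ⇌ T | t-SNARE complex preassembly |
| R2 | T + Syb ⇌ Pin | SNAREpin assembly |
| R3 | Pin + SM ⇌ Pin·SM | pattern-2 binding (SM on the assembled SNAREpin) |
| R4 | Pin → Fused | basal fusion, rate kf0 |
| R5 | Pin·SM → Fused·SM | SM-stimulated fusion, rate kf1 ≫ kf0 |
| R6 | Syx + SM ⇌ Syx·SM(closed) | pattern-1 closed binding — neuronal only |
| R7 | DF + Syx·SM(closed) ⇌ DF·SM + Syx | displacement factor — extended motif only |

The **yeast** motif (Sso1p/Sec9p/Snc1-2p regulated by Sec1p) is the pure
cascade R1–R5. The **neuronal** motif (syntaxin-1/SNAP25/VAMP2 regulated by
Munc18-1) adds R6: Munc18-1 clamps monomeric syntaxin-1 in a closed
conformation that cannot enter assembly; the closed complex participates in
no other reaction, so escape is only through the reverse of R6. R6 turns
the cascade into a feedback loop — Pin·SM formation (R3) sequesters SM away
from syntaxin, relieving the inhibition. The **mutant neuronal** motif
deletes R6 (the constitutively open syntaxin mutant) and is structurally
isomorphic to the yeast cascade under renaming. The **extended** motif adds
an abstract displacement factor (a Munc13/Tomosyn-like activity, default
1 μM) that strips SM off the closed complex via a single reversible
exchange, R7; it leaves the feedback topology intact.

Fusion is modeled as an irreversible state change: the fused species carry
the same moieties as their precursors, so total protein mass is conserved
by construction. The *fusion level* is the fraction of the v-SNARE moiety
residing in fused species — a dimensionless number in [0, 1].

Assumptions: well-mixed mass action in a single compartment; μM/seconds
units; stoichiometric coefficients of 1 throughout the shipped motifs; no
calcium triggering, docking intermediates, or N-peptide sub-binding-site
detail (the two SM binding modes are collapsed into pattern 1 and
pattern 2).

## Readout: the plateau, not t → ∞

All binding steps are reversible and both fusion steps are irreversible, so
for any kf0 > 0 the true t → ∞ fusion level is 1 at every SM dose. The
dose-dependent quantity of interest is the fusion level reached on the
assay time scale. The package defines it as the *plateau readout*:
integrate to t_max = 5000 s and report the fusion level at the first
reporting point where d(fusion)/dt, evaluated exactly from the mass-action
fluxes, drops below ε = 1e−6 s⁻¹ while non-increasing (the non-increase
guard keeps the initial rise, where the rate passes through zero at t = 0,
from being mistaken for a plateau). If the criterion is never met the value
at t_max is reported and flagged.

## Default rate constants

The shipped defaults are configuration, not measurements:

| label | kf | kr | note |
|---|---|---|---|
| R1 | 1.0 μM⁻¹s⁻¹ | 0.1 s⁻¹ | |
| R2 | 1.0 μM⁻¹s⁻¹ | 0.02 s⁻¹ | |
| R3 | 5.0 μM⁻¹s⁻¹ | 0.02 s⁻¹ | Kd = 4 nM |
| R4 | 5e−5 s⁻¹ | 0 | basal fusion, τ ≈ 5.6 h |
| R5 | 2e−2 s⁻¹ | 0 | stimulated fusion, 400 × basal |
| R6 | 8.0 μM⁻¹s⁻¹ | 1.3e−3 s⁻¹ | Kd ≈ 0.16 nM, tightest binding |
| R7 | 1.0 μM⁻¹s⁻¹ | 0.1 s⁻¹ | |

Choice rationale. Associations sit in the 1–10 μM⁻¹s⁻¹ range typical of
protein–protein binding; dissociations are slow (strong-binding regime).
The closed Munc18-syntaxin complex is the tightest and fastest-forming
interaction — that is what makes it an effective stoichiometric trap — and
its dissociation is slower than that of the SNAREpin·SM complex. Basal
fusion is slow relative to the 5000 s readout horizon (so the zero-SM
plateau is partial, ≈ 0.20) while SM-stimulated fusion is fast relative to
it (so the SM-saturated plateau approaches 1). Within that regime the
constants were calibrated once so that the four motifs reproduce the
qualitative system behaviors the models are built to exhibit — monotone
hyperbolic yeast/mutant responses, a biphasic neuronal response peaking at
the syntaxin concentration, and overexpression scenarios that flip sign
across the optimum — and not revisited. Cascade rates R1–R5 are *shared*
across all motifs so that any behavioral difference is attributable to
topology alone.

Why a biphasic response emerges: below 4.5 μM SM, pattern-2 binding and
fast stimulated fusion soak up SM productively; above 4.5 μM (total
syntaxin), the excess SM has no SNAREpin left to bind and instead titrates
free syntaxin into the closed trap, throttling assembly itself. The
maximum therefore sits at SM ≈ [Syx]₀ = 4.5 μM — a stoichiometric landmark
robust to ±30% rate perturbations, as the robustness analysis shows.

## Initial conditions

SNARE monomers (Syx, S25, Syb) start at 4.5 μM; all complexes at 0; the SM
dose is the scanned input, 0–6 μM (default grid step 0.05 μM for optimum
location, coarser for shape classification). SNARE concentrations in the
0.1–100 μM range are admissible inputs. The extended motif's DF starts at
1.0 μM (configurable).

## Numerics

* **Integrator** — LSODA (stiff-capable, variable step) via
  `scipy.integrate.solve_ivp`, rtol 1e−6, atol 1e−9 μM, 500-point reporting
  grid. Any stiff-capable method meeting the tolerance contract is
  acceptable; halving the tolerances moves plateau readouts by < 1e−4.
* **Stochastic oracle** — exact Gillespie direct method (numba-compiled),
  with copy numbers x = Ω·c and stochastic constants k·Ω^(1−order)/∏sᵢ!.
  Reversible reactions are unrolled into two irreversible channels. Used
  only to cross-check the ODE compilation: at Ω = 10⁴ molecules/μM the mean
  of 200 runs must track the ODE fusion level within 3 standard errors at
  five checkpoints over 0–10 s (SM at 3 μM so every reaction channel is
  live); the horizon and checkpoints are package choices made for
  desk-scale runtime.
* **Conservation** — each protein moiety defines a conserved linear
  combination (coefficients = moiety counts); trajectories keep every total
  within relative 1e−6. The test suite independently verifies the laws lie
  in the exact left null space of the stoichiometric matrix (rational
  elimination via sympy).
* **Classification** — monotone labels tolerate dips up to 1e−3 fusion
  units; biphasic requires a rise and a fall both exceeding the tolerance;
  flat means total variation below it. Ties at the maximum break to the
  smallest dose.
* **Optimum location** — dense grid scan at the requested resolution, then
  golden-section refinement inside the bracketing interval; boundary maxima
  are returned without refinement. "Bifurcation point" is kept as an alias
  for the optimum SM dose: in this literature the word denotes the biphasic
  dose-response maximum, not a dynamical-systems bifurcation of attractors.
* **LHS** — every kf and kr is an independent dimension sampled uniformly
  on [(1−v)k, (1+v)k] with one draw per equal-width stratum
  (numpy Generator, seeded). v = 0.30 and n = 2000 reproduce the original
  robustness protocol; the shipped analysis and tests use n = 50 and n = 20
  respectively, which already pin the preservation fraction at 1.0 under
  defaults. Shape preservation (same label as nominal) is this package's
  robustness criterion.

## Synthetic assay data

`ssnm.synth` emulates dequenching-based lipid-mixing traces: the simulated
fusion level plus additive Gaussian noise, clamped to [0, 1−1e−6], sampled
at a fixed interval. It reproduces what the analysis chain needs —
normalized, noisy, monotone-in-expectation traces — and nothing else: no
photobleaching, inner-filter effects, detergent-normalization drift, or
liposome size heterogeneity. Passing tests on synthetic traces therefore
validate the transform and classification machinery, not instrument
physics. The rounds transform is the Poisson convention,
rounds = −ln(1 − f): if each liposome undergoes Poisson-many fusion events,
the normalized signal saturates as 1 − e^(−rounds). It is isolated behind
one function so an alternative calibration can be substituted.

## Known limitations

* The reaction sets are reconstructed from published network descriptions;
  the originating study's exact supplementary equations and rate constants
  were not available, so quantitative fusion levels here are
  model-conditional — only the qualitative shapes, the stoichiometric
  optimum, and the structural results (isomorphism, conservation) are
  claims the package defends.
* The plateau readout depends on (t_max, ε); dose-response magnitudes (not
  shapes) shift with the horizon.
* Both fused species are absorbing; whether SNAREpin·SM fusion products
  should recycle SM is an open modeling question — here they do not.
* The displacement factor's concentration and rates are package defaults;
  only the topological claim (feedback intact ⇒ still biphasic) is tested.
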