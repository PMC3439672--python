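# ssnm — SM-SNARE network motif kinetics

Mass-action kinetic modeling of how Sec1/Munc18 (SM) proteins regulate
SNARE-driven exocytic membrane fusion, for systems biologists comparing
the *yeast* secretory pathway (Sso1p/Sec9p/Snc1-2p + Sec1p) with the
*neuronal* synaptic pathway (syntaxin-1/SNAP25/VAMP2 + Munc18-1).

The two systems share a conserved assembly cascade,

```
Syx + S25 ⇌ T          (t-SNARE complex)
T  + Syb ⇌ Pin         (SNAREpin)
Pin + SM ⇌ Pin·SM      (pattern-2 SM binding)
Pin  → Fused            (basal fusion,      kf0)
Pin·SM → Fused·SM       (stimulated fusion, kf1 ≫ kf0)
```

but the neuronal system has one extra edge — Munc18-1 clamping monomeric
syntaxin-1 in a *closed* conformation (`Syx + SM ⇌ Syx·SM_closed`,
pattern-1 binding) that cannot enter assembly. That single reaction turns
the cascade into a feedback loop and changes the steady-state fusion
response to SM dose qualitatively: the yeast cascade responds
hyperbolically (more SM, more fusion), while the neuronal network is
*biphasic*, peaking where the SM dose equals the syntaxin concentration
(4.5 μM under the standard initial conditions) and declining beyond it as
excess SM titrates syntaxin into the closed trap. Deleting the closed
binding in silico — the open-syntaxin mutant — collapses the response back
to the yeast shape, and the biphasic curve explains why SM overexpression
raises fusion in some experimental systems and lowers it in others.

The package provides: reaction-network → ODE compilation with structural
validation and moiety-conservation laws; stiff ODE and exact Gillespie
simulation; plateau ("steady-state") fusion readout and dose-response
scans; shape classification and optimum location; in-silico reaction
deletion; Latin-hypercube parameter robustness; synthetic lipid-mixing
fluorescence traces and the fusion-rounds transform (−ln(1−f)); YAML and
SBML L3V1 model documents; and a CLI.

## Worked example

```python
import numpy as np
from ssnm import neuronal_ssnm, default_rates, dose_response, classify_response

model = neuronal_ssnm()                      # 10 species, 6 reactions
rates = default_rates("neuronal")
doses = np.round(np.arange(0, 6.0001, 0.05), 6)
dr = dose_response(model, rates, "nSM", doses)
cls = classify_response(dr)
print(cls.shape, cls.argmax_dose, round(cls.max_fusion, 3))
```

prints

```
biphasic 4.5 0.983
```

— the wildtype neuronal dose-response is biphasic and plateau fusion is
maximal at an Munc18-1 dose of 4.5 μM, exactly the syntaxin-1 initial
concentration, where 98.3% of the v-SNARE has fused by the plateau. The
same scan on `yeast_ssnm()` or `mutant_neuronal_ssnm()` classifies
`monotonic_increasing` with the maximum at the top of the scanned range
(6 μM).

Or from the shell:

```sh
ssnm scan --model neuronal --grid 0:6:0.05 --out dr.tsv
ssnm optimum --model neuronal --lo 0 --hi 6 --step 0.05
ssnm mutate --model neuronal --drop R6 --out mutant.yaml
ssnm classify --model mutant.yaml
```

## Analysis scripts

`analysis/01…06` are narrative drivers that regenerate every table under
`results/`: fusion curves at five SM doses, the four-motif dose-response
comparison, the in-silico R6 deletion, the two overexpression scenarios,
the ±30% LHS robustness report, and synthetic assay traces.

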