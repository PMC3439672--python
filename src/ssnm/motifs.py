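"""The four SM-SNARE network motifs (SSNMs) and their default rate set.

The motifs describe exocytic membrane fusion in two systems:

* **yeast** — a cascade: Sso1p (ySyx) and Sec9p (yS25) preassemble into the
  t-SNARE complex, Snc1/2p (ySyb) joins to form the SNAREpin, and the SM
  protein Sec1p (ySM) stimulates fusion by binding the assembled SNAREpin
  ("pattern 2" binding).
* **neuronal** — the same cascade with syntaxin-1 (nSyx), SNAP25 (nS25),
  VAMP2 (nSyb) and Munc18-1 (nSM), plus one extra reaction: Munc18-1 clamps
  monomeric syntaxin-1 in a *closed* conformation ("pattern 1" binding) that
  cannot enter SNAREpin assembly.  That single edge converts the cascade
  into a feedback-loop topology: SNAREpin·SM formation sequesters Munc18-1
  away from syntaxin-1, relieving the inhibition it would otherwise exert.
* **mutant_neuronal** — the neuronal motif with the closed-binding reaction
  deleted (emulating the constitutively open syntaxin-1 L165A/E166A mutant);
  topologically it collapses back onto the yeast cascade.
* **extended_neuronal** — the neuronal motif plus an abstract displacement
  factor (DF, a Munc13/Tomosyn-like activity) that strips Munc18-1 off the
  closed complex: DF + closed ⇌ DF·SM + free syntaxin.

The exact rate constants of the original kinetic study live in a supplement
that is not reproduced here; the values below are this package's documented
defaults, chosen in the physically reasonable strong-binding regime
(associations of order 1 μM⁻¹s⁻¹, dissociations of order 10⁻³–10⁻¹ s⁻¹,
fusion slow relative to binding) and verified to reproduce the qualitative
system behaviours: hyperbolic SM dose response in yeast and mutant, biphasic
("bifurcation") response in the wildtype and DF-extended neuronal motifs
with the optimum at SM ≈ syntaxin.  They are configuration, not physics.
"""

from __future__ import annotations

from typing import Dict, Tuple

from .network import NetworkModel, RateSet, Reaction, Species

__all__ = [
    "MOTIF_NAMES",
    "yeast_ssnm",
    "neuronal_ssnm",
    "mutant_neuronal_ssnm",
    "extended_neuronal_ssnm",
    "default_rates",
    "get_motif",
    "SNARE_INITIAL_UM",
    "SM_SCAN_RANGE_UM",
]

#: initial concentration of each SNARE protein (μM)
SNARE_INITIAL_UM = 4.5
#: the SM dose range scanned in all dose-response experiments (μM)
SM_SCAN_RANGE_UM = (0.0, 6.0)

MOTIF_NAMES = ("yeast", "neuronal", "mutant_neuronal", "extended_neuronal")

# Shared cascade rates (R1-R5) keep the motifs comparable by construction;
# the neuronal-specific closed binding (R6) dissociates more slowly than
# SNAREpin·SM (R3) — the closed Munc18-syntaxin complex is the tight one.
# Fusion rate constants satisfy kf1 >> kf0: SM stimulates fusion, it is not
# obligatory for it (SNAREs alone fuse, slowly).
_DEFAULT_RATES: Dict[str, Tuple[float, float]] = {
    "R1": (1.0, 0.1),     # Syx + S25 ⇌ t-SNARE complex
    "R2": (1.0, 0.02),    # t-SNARE + Syb ⇌ SNAREpin
    "R3": (5.0, 0.02),    # SNAREpin + SM ⇌ SNAREpin·SM (tight pattern-2 binding)
    "R4": (5e-5, 0.0),    # SNAREpin → fused            (basal, kf0)
    "R5": (2e-2, 0.0),    # SNAREpin·SM → fused·SM      (stimulated, kf1)
    "R6": (8.0, 1.3e-3),  # Syx + SM ⇌ closed Syx·SM    (fast, tight pattern-1 binding)
    "R7": (1.0, 0.1),     # DF + closed ⇌ DF·SM + Syx   (extended only)
}

_MOTIF_LABELS = {
    "yeast": ("R1", "R2", "R3", "R4", "R5"),
    "neuronal": ("R1", "R2", "R3", "R4", "R5", "R6"),
    "mutant_neuronal": ("R1", "R2", "R3", "R4", "R5"),
    "extended_neuronal": ("R1", "R2", "R3", "R4", "R5", "R6", "R7"),
}


def _cascade(prefix: str, name: str) -> NetworkModel:
    """The five-reaction SNARE assembly/fusion cascade with ``prefix`` naming."""
    p = prefix
    syx, s25, syb, sm = f"{p}Syx", f"{p}S25", f"{p}Syb", f"{p}SM"
    t, pin, pinsm = f"{p}T", f"{p}Pin", f"{p}PinSM"
    fused, fusedsm = f"{p}Fused", f"{p}FusedSM"
    species = [
        Species(syx, {syx: 1}, "monomer"),
        Species(s25, {s25: 1}, "monomer"),
        Species(syb, {syb: 1}, "monomer"),
        Species(sm, {sm: 1}, "monomer"),
        Species(t, {syx: 1, s25: 1}, "complex"),
        Species(pin, {syx: 1, s25: 1, syb: 1}, "complex"),
        Species(pinsm, {syx: 1, s25: 1, syb: 1, sm: 1}, "complex"),
        Species(fused, {syx: 1, s25: 1, syb: 1}, "fused"),
        Species(fusedsm, {syx: 1, s25: 1, syb: 1, sm: 1}, "fused"),
    ]
    r = _DEFAULT_RATES
    reactions = [
        Reaction("R1", {syx: 1, s25: 1}, {t: 1}, *r["R1"]),
        Reaction("R2", {t: 1, syb: 1}, {pin: 1}, *r["R2"]),
        Reaction("R3", {pin: 1, sm: 1}, {pinsm: 1}, *r["R3"]),
        Reaction("R4", {pin: 1}, {fused: 1}, *r["R4"]),
        Reaction("R5", {pinsm: 1}, {fusedsm: 1}, *r["R5"]),
    ]
    initials = {s.name: 0.0 for s in species}
    initials[syx] = initials[s25] = initials[syb] = SNARE_INITIAL_UM
    initials[sm] = 0.0
    return NetworkModel(
        name=name,
        species=species,
        reactions=reactions,
        initial_concentrations=initials,
        readout_moiety=syb,
    )


def yeast_ssnm() -> NetworkModel:
    """Cascade-like yeast SSNM (Sso1p/Sec9p/Snc1-2p/Sec1p); 9 species, 5 reactions."""
    return _cascade("y", "yeast")


def mutant_neuronal_ssnm() -> NetworkModel:
    """Neuronal SSNM with the closed Munc18-syntaxin binding removed.

    Structurally isomorphic to the yeast cascade under the y↔n renaming,
    which is the point: deleting one binding mode collapses the feedback
    topology back onto the cascade.
    """
    return _cascade("n", "mutant_neuronal")


def neuronal_ssnm() -> NetworkModel:
    """Feedback-loop-like wildtype neuronal SSNM; 10 species, 6 reactions.

    Adds the closed binding mode R6: nSyx + nSM ⇌ nSyxSM_closed.  The closed
    complex is a dead end for assembly — it participates in no other
    reaction, and escape is only through the reverse of R6.
    """
    m = _cascade("n", "neuronal")
    closed = Species("nSyxSM_closed", {"nSyx": 1, "nSM": 1}, "complex")
    m.species.append(closed)
    m.initial_concentrations[closed.name] = 0.0
    m.reactions.append(
        Reaction("R6", {"nSyx": 1, "nSM": 1}, {"nSyxSM_closed": 1}, *_DEFAULT_RATES["R6"])
    )
    return m


def extended_neuronal_ssnm(df_initial_um: float = 1.0) -> NetworkModel:
    """Neuronal SSNM plus a displacement factor; 12 species, 7 reactions.

    R7 models Munc13/Tomosyn-like displacement as a single reversible
    exchange, DF + nSyxSM_closed ⇌ DFnSM + nSyx, releasing syntaxin-1 back
    into the assembly-competent pool.
    """
    m = neuronal_ssnm()
    m.name = "extended_neuronal"
    df = Species("DF", {"DF": 1}, "monomer")
    dfnsm = Species("DFnSM", {"DF": 1, "nSM": 1}, "complex")
    m.species.extend([df, dfnsm])
    m.initial_concentrations["DF"] = float(df_initial_um)
    m.initial_concentrations["DFnSM"] = 0.0
    m.reactions.append(
        Reaction(
            "R7",
            {"DF": 1, "nSyxSM_closed": 1},
            {"DFnSM": 1, "nSyx": 1},
            *_DEFAULT_RATES["R7"],
        )
    )
    return m


def default_rates(motif: str) -> RateSet:
    """The package's documented default rate set for a catalog motif.

    Cascade labels (R1-R5) share values across all motifs so dose-response
    differences are attributable to topology alone.
    """
    if motif not in _MOTIF_LABELS:
        raise KeyError(f"unknown motif {motif!r}; known: {', '.join(_MOTIF_LABELS)}")
    return {lab: _DEFAULT_RATES[lab] for lab in _MOTIF_LABELS[motif]}


_BUILDERS = {
    "yeast": yeast_ssnm,
    "neuronal": neuronal_ssnm,
    "mutant_neuronal": mutant_neuronal_ssnm,
    "extended_neuronal": extended_neuronal_ssnm,
}


def get_motif(name: str) -> NetworkModel:
    """Build a catalog motif by name (accepts 'mutant' and 'extended' shorthands)."""
    aliases = {"mutant": "mutant_neuronal", "extended": "extended_neuronal"}
    key = aliases.get(name, name)
    if key not in _BUILDERS:
        raise KeyError(f"unknown motif {name!r}; known: {', '.join(_BUILDERS)}")
    return _BUILDERS[key]()


def sm_species(model: NetworkModel) -> str:
    """Name of the free SM monomer in a catalog-style model."""
    for s in model.species:
        if s.role == "monomer" and s.name.endswith("SM"):
            return s.name
    raise ValueError(f"model {model.name!r} has no SM monomer species")
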