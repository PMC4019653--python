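"""State-vector layout of the combined cell-cycle model.

The model tracks 25 species (arbitrary concentration units, time in
fractions of the cell-cycle time Tc).  Each species carries a set of
moiety tags used by the observable layer (e.g. every species containing
a cyclin A moiety is tagged ``"cyclinA"`` so that *total* cyclin A can be
computed by metadata rather than by a hard-coded index list).
"""

from __future__ import annotations

# name -> frozenset of moiety tags
SPECIES_TAGS: dict[str, frozenset[str]] = {
    # --- entry block (growth signalling, cyclin D, Rb/E2F) ---
    "ERG": frozenset({"entry"}),               # early-response genes (MAPK-like signal)
    "DRG": frozenset({"entry"}),               # delayed-response genes; reset at division
    "CycD": frozenset({"cyclinD", "entry"}),   # CycD:Cdk4/6, free
    "CycD_Kip": frozenset({"cyclinD", "kip1", "entry"}),  # CycD:Cdk4/6:Kip1
    "Rb": frozenset({"rb"}),                   # hypophosphorylated Rb, free
    "pRb": frozenset({"rb"}),                  # CycD-phosphorylated Rb
    "ppRb": frozenset({"rb"}),                 # hyperphosphorylated Rb
    "E2F_Rb": frozenset({"rb", "e2f"}),        # E2F sequestered by Rb
    "E2F": frozenset({"e2f"}),                 # free, transcriptionally active E2F
    "pE2F": frozenset({"e2f"}),                # Cdk-phosphorylated E2F (APC/C substrate)
    # --- cyclin E / CKI ---
    "CycE": frozenset({"cyclinE"}),            # CycE:Cdk2, active
    "CycE_Kip": frozenset({"cyclinE", "kip1"}),
    "Kip1": frozenset({"kip1"}),               # free CKI (p27-like)
    # --- cyclin A (two Cdk pools acting in unison) ---
    "CycA2": frozenset({"cyclinA"}),           # CycA:Cdk2
    "CycA1": frozenset({"cyclinA"}),           # CycA:Cdk1
    "CycA_Kip": frozenset({"cyclinA", "kip1"}),
    # --- cyclin B ---
    "CycB": frozenset({"cyclinB"}),            # total CycB:Cdk1 (active + Tyr15-phosphorylated)
    "actCycB": frozenset({"cyclinB_active"}),  # active sub-pool of CycB (not double counted)
    # --- mitotic regulators (active fractions unless noted) ---
    "Wee1": frozenset({"regulator"}),
    "Cdc25": frozenset({"regulator"}),
    "Cdh1": frozenset({"regulator"}),
    "Cdc20T": frozenset({"regulator"}),        # total Cdc20
    "Cdc20A": frozenset({"regulator"}),        # APC/C-bound, active Cdc20
    "IEP": frozenset({"regulator"}),           # intermediary enzyme delaying APC activation
    "TFAB": frozenset({"regulator"}),          # shared G2 transcription factor for cyclins A/B
}

SPECIES_NAMES: tuple[str, ...] = tuple(SPECIES_TAGS)
N_SPECIES: int = len(SPECIES_NAMES)
SPECIES_INDEX: dict[str, int] = {n: i for i, n in enumerate(SPECIES_NAMES)}

#: species whose levels make up the measured "total cyclin A" channel
CYCLIN_A_SPECIES = tuple(n for n, t in SPECIES_TAGS.items() if "cyclinA" in t)
#: species whose levels make up the measured "total cyclin B" channel
CYCLIN_B_SPECIES = tuple(n for n, t in SPECIES_TAGS.items() if "cyclinB" in t)

#: conserved Rb moiety (no Rb synthesis or degradation in the model)
RB_MOIETY = tuple(n for n, t in SPECIES_TAGS.items() if "rb" in t)

#: active/total pairs for the active<=total structural invariant
ACTIVE_TOTAL_PAIRS = (("actCycB", "CycB"), ("Cdc20A", "Cdc20T"))

#: G1 variables reset to their start-of-cycle values at each division
DEFAULT_RESET_SPECIES = ("DRG", "CycD", "CycD_Kip")
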