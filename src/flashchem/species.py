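"""Chemical species tracked through the radiolysis chemical stage.

The simulation follows the primary radiolytic species of liquid water:
the hydrated electron, the hydroxyl radical, the hydronium ion, the
hydrogen radical and the hydroxide ion, plus the two stable molecular
products (H2 and H2O2) that accumulate through radical-radical reactions.
"""

from __future__ import annotations

from enum import IntEnum


class SpeciesKind(IntEnum):
    """Closed set of simulated species; every particle carries exactly one."""

    E_HYDRATED = 0
    OH_RADICAL = 1
    H3O_PLUS = 2
    H_RADICAL = 3
    OH_MINUS = 4
    H2 = 5
    H2O2 = 6


N_SPECIES = len(SpeciesKind)

#: Short labels used in CSV headers and CLI output.
SPECIES_LABELS = {
    SpeciesKind.E_HYDRATED: "e_h",
    SpeciesKind.OH_RADICAL: "OH",
    SpeciesKind.H3O_PLUS: "H3O",
    SpeciesKind.H_RADICAL: "H",
    SpeciesKind.OH_MINUS: "OHm",
    SpeciesKind.H2: "H2",
    SpeciesKind.H2O2: "H2O2",
}

LABEL_TO_SPECIES = {v: k for k, v in SPECIES_LABELS.items()}
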