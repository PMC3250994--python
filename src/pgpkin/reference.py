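"""Published reference values for ¹¹C-desmethylloperamide in mice.

These are the literature-reported quantities for the three experimental
groups — wild-type mice pre-injected with saline (WT), wild-type mice
pre-injected with 50 mg/kg cyclosporine (CYCLO, P-gp chemically blocked),
and Mdr1a knock-out mice (KO, P-gp genetically absent):

* one-tissue-compartment rate constants K1 (mL/cc/min) and k2 (1/min) per
  animal, with the printed K1/k2 ratio;
* the HPLC-measured parent fraction of plasma radioactivity at 1, 10 and
  30 min post-injection per group;
* the mean plasma-to-whole-blood activity ratio (0.64) and the dispersion
  time constant of the microvolumetric blood counter (28 s).

They seed the synthetic cohort generator and serve as inputs to the
statistics layer; nothing in the fitting code depends on them.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "GROUPS",
    "RATE_CONSTANTS",
    "PRINTED_K1_K2",
    "PARENT_FRACTIONS",
    "PLASMA_WB_RATIO",
    "TAU_DISP_S",
    "rate_table",
]

#: Canonical group labels used throughout the package.
GROUPS = ("WT-saline", "WT-cyclo", "KO")

#: Per-animal (K1 [mL/cc/min], k2 [1/min]) pairs from the published
#: one-tissue-compartment fits, three animals per group.
RATE_CONSTANTS: dict[str, list[tuple[float, float]]] = {
    "WT-saline": [(0.054, 0.190), (0.042, 0.120), (0.027, 0.059)],
    "KO": [(0.190, 0.120), (0.230, 0.095), (0.190, 0.100)],
    "WT-cyclo": [(0.250, 0.150), (0.120, 0.063), (0.180, 0.086)],
}

#: The K1/k2 ratios as printed (two decimals) alongside the rate constants.
PRINTED_K1_K2: dict[str, list[float]] = {
    "WT-saline": [0.28, 0.35, 0.46],
    "KO": [1.58, 2.42, 1.90],
    "WT-cyclo": [1.66, 1.90, 2.09],
}

#: Parent fraction of plasma activity (unitless) at (time [min p.i.], fraction).
#: Values are the reported group means; the implied anchor f(0) = 1 is added
#: by the parent-fraction model, not stored here.
PARENT_FRACTIONS: dict[str, list[tuple[float, float]]] = {
    "WT-saline": [(1.0, 0.95), (10.0, 0.72), (30.0, 0.53)],
    "WT-cyclo": [(1.0, 0.95), (10.0, 0.54), (30.0, 0.23)],
    "KO": [(1.0, 0.98), (10.0, 0.51), (30.0, 0.34)],
}

#: Mean plasma-to-whole-blood activity ratio used as a single scalar
#: correction factor (the time-resolved measurements were 0.67/0.49/0.67).
PLASMA_WB_RATIO: float = 0.64

#: Dispersion time constant of the arterial blood-counter line (seconds).
TAU_DISP_S: float = 28.0


def rate_table() -> "np.ndarray":
    """All nine (K1, k2) pairs as an array in group order WT, KO, CYCLO."""
    rows = []
    for group in ("WT-saline", "KO", "WT-cyclo"):
        rows.extend(RATE_CONSTANTS[group])
    return np.asarray(rows)
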