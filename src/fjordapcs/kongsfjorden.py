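"""Published reference values for the Kongsfjorden study system.

These constants are the printed summary statistics of the Kongsfjorden
(West Svalbard) source-apportionment study that this package implements:
the rotated three-component loading matrix of the 18 measured water-column
parameters with its broken-stick significance pattern, and the proglacial
river concentrations used for river-endmember and estuarine-removal
arithmetic.  They serve as fixtures for reproduction checks and as the
loading template of the synthetic generator; they are inputs, not outputs,
of this package.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "PARAMETERS",
    "REFERENCE_LOADINGS",
    "REFERENCE_SIGNIFICANT",
    "REFERENCE_CLUSTERS",
    "RIVER_DMN_NG_L",
    "RIVER_DFE_NG_L",
    "FJORD_SURFACE_DFE_NG_L",
    "STUDY_SALINITY_RANGE",
]

PARAMETERS = [
    "salinity", "temperature", "NO3", "NO2", "SiOH4", "PO4", "AT", "CT",
    "dAl", "dV", "dFe", "dMn", "dCo", "dNi", "dCu", "dZn", "dCd", "dPb",
]

# Rotated loadings on the three retained components: PC1 conservative
# mixing / freshwater input, PC2 pelagic processes and water masses,
# PC3 benthic processes.
REFERENCE_LOADINGS = pd.DataFrame(
    np.array([
        [-0.98,  0.10,  0.07],   # salinity
        [-0.25, -0.90, -0.06],   # temperature
        [-0.15,  0.96,  0.09],   # NO3
        [-0.18,  0.97,  0.12],   # NO2
        [ 0.13,  0.59,  0.65],   # SiOH4
        [-0.25,  0.91,  0.23],   # PO4
        [-0.97,  0.13,  0.07],   # AT
        [-0.85,  0.48,  0.11],   # CT
        [ 0.99, -0.07, -0.09],   # dAl
        [-0.98,  0.05, -0.03],   # dV
        [-0.21,  0.23,  0.87],   # dFe
        [ 0.95, -0.02,  0.14],   # dMn
        [ 0.99, -0.02, -0.06],   # dCo
        [ 0.98,  0.03, -0.11],   # dNi
        [ 0.55, -0.34,  0.60],   # dCu
        [-0.17,  0.26,  0.80],   # dZn
        [-0.06,  0.93,  0.15],   # dCd
        [ 0.80,  0.05, -0.07],   # dPb
    ]),
    index=PARAMETERS, columns=["PC1", "PC2", "PC3"],
)

# Which loadings the study's broken-stick screen flagged as significant.
_SIG = {
    "salinity": ["PC1"], "temperature": ["PC2"], "NO3": ["PC2"],
    "NO2": ["PC2"], "SiOH4": ["PC2", "PC3"], "PO4": ["PC2"], "AT": ["PC1"],
    "CT": ["PC1"], "dAl": ["PC1"], "dV": ["PC1"], "dFe": ["PC3"],
    "dMn": ["PC1"], "dCo": ["PC1"], "dNi": ["PC1"], "dCu": ["PC3"],
    "dZn": ["PC3"], "dCd": ["PC2"], "dPb": ["PC1"],
}
REFERENCE_SIGNIFICANT = pd.DataFrame(
    {c: [c in _SIG[p] for p in PARAMETERS] for c in ["PC1", "PC2", "PC3"]},
    index=PARAMETERS,
)

# Reported five-cluster grouping of the parameters in loading space.
REFERENCE_CLUSTERS = [
    frozenset({"salinity", "AT", "CT", "dV"}),
    frozenset({"dAl", "dMn", "dCo", "dNi", "dPb"}),
    frozenset({"NO3", "NO2", "PO4", "dCd"}),
    frozenset({"SiOH4", "dFe", "dCu", "dZn"}),
    frozenset({"temperature"}),
]

# Dissolved Mn measured at the three proglacial river outlets (ng/L):
# Bayelva (BR), Midtre Lovenbreen (ML), Austre Lovenbreen (AL).
RIVER_DMN_NG_L = {"BR": 9710.0, "ML": 22000.0, "AL": 6850.0}

# Dissolved Fe at the river outlets bounding the estuarine-removal range,
# and the fjord surface-water mean it is compared against (ng/L).
RIVER_DFE_NG_L = {"BR": 348.0, "AL": 7400.0}
FJORD_SURFACE_DFE_NG_L = 188.0

# Observed fjord salinity range of the study (min at the glacier front,
# max in Atlantic Water at the outer station).
STUDY_SALINITY_RANGE = (32.07, 34.91)
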