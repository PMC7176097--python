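"""Published Ebro Delta reference values used as worked-example inputs.

These are the printed landscape figures for the three studied wetland types
(the Alfacs salt marsh, the Encanyissada brackish lagoon and the Filtre
biologic restored freshwater wetland): Corine Land-Cover surfaces, the
extrapolated per-type annual C and CO2-equivalent balances, and the per-site
annual areal balance pairs.  They serve as desk-scale inputs for consistency
checks (summing the per-type balances, back-solving the annual CH4-C flux
from each (C, CO2-eq) pair); they are not outputs of this package's pipeline.
"""

from __future__ import annotations

#: wetland type -> (site label, surface ha, C balance Tn y-1, CO2-eq balance Tn y-1)
LANDSCAPE_TABLE: dict[str, tuple[str, float, float, float]] = {
    "salt_marsh": ("ALFA", 1292.43, -546.51, -378.17),
    "brackish": ("ENCA", 1797.40, -4514.50, -2224.97),
    "freshwater": ("FBIO", 563.06, -1225.37, -358.14),
}

#: site label -> (annual C balance g C m-2 y-1, annual GWP balance g CO2-eq m-2 y-1)
ANNUAL_BALANCE_PAIRS: dict[str, tuple[float, float]] = {
    "ALFA": (-42.0, -29.0),
    "ENCA": (-251.0, -124.0),
    "FBIO": (-210.0, -64.0),
}

#: wetland type -> surface occupied in the delta, hectares
SURFACES_HA: dict[str, float] = {k: v[1] for k, v in LANDSCAPE_TABLE.items()}
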