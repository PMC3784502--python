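"""Unit conversions between concentrations and per-cell copy numbers.

Concentrations are nanomolar (nM) throughout the package; time is seconds.
Copy-number conversions use the cytoplasmic volume of a typical epithelial
cell together with the three-digit Avogadro constant, which reproduces the
printed copy numbers (10 nM = 3,154 copies, 100 nM = 31,540 copies) exactly
after rounding.
"""

from __future__ import annotations

#: Avogadro constant, rounded to the precision used for copy-number tables.
AVOGADRO = 6.022e23

#: Cytoplasmic volume of an epithelial cell, litres.
CELL_VOLUME_L = 5.2375e-13


def nm_to_copies(conc_nm: float, volume_l: float = CELL_VOLUME_L) -> float:
    """Convert a concentration in nM to molecule copies per cell."""
    return conc_nm * 1e-9 * AVOGADRO * volume_l


def copies_to_nm(copies: float, volume_l: float = CELL_VOLUME_L) -> float:
    """Convert molecule copies per cell to a concentration in nM."""
    return copies / (1e-9 * AVOGADRO * volume_l)


def molec_per_s_to_nm_per_s(rate: float, volume_l: float = CELL_VOLUME_L) -> float:
    """Convert a zeroth-order rate in molecules/s to nM/s."""
    return copies_to_nm(rate, volume_l)
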