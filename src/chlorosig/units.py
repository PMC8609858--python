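"""Unit converters for the interface boundary.

Everything inside the package is SI: metres, seconds, cubic metres,
μmol photons. Laboratory conventions (cells/mL, μm) are converted here,
exactly once, at the boundary.
"""

#: cells·mL⁻¹ → cells·m⁻³
CELLS_PER_ML_TO_PER_M3 = 1.0e6

#: 1 mL in m³
ML_TO_M3 = 1.0e-6


def cells_per_ml_to_per_m3(density: float) -> float:
    """Convert a cell density from cells/mL to cells/m³."""
    return density * CELLS_PER_ML_TO_PER_M3


def um_to_m(length_um: float) -> float:
    """Convert micrometres to metres."""
    return length_um * 1.0e-6


def m_to_um(length_m: float) -> float:
    """Convert metres to micrometres."""
    return length_m * 1.0e6


def ml_to_m3(volume_ml: float) -> float:
    """Convert millilitres to cubic metres."""
    return volume_ml * ML_TO_M3
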