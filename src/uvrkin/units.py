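"""Unit conventions and conversions.

Internally everything runs in micromolar (µM) and seconds. Bimolecular rate
constants are quoted in the literature in M⁻¹ s⁻¹; the single conversion
utility below is the only place that conversion happens.
"""

#: multiply a bimolecular constant in M⁻¹ s⁻¹ by this to get µM⁻¹ s⁻¹
M_TO_UM = 1e-6


def per_molar_to_per_micromolar(k: float) -> float:
    """Convert a bimolecular rate constant from M⁻¹ s⁻¹ to µM⁻¹ s⁻¹."""
    return k * M_TO_UM


def per_micromolar_to_per_molar(k: float) -> float:
    """Convert a bimolecular rate constant from µM⁻¹ s⁻¹ to M⁻¹ s⁻¹."""
    return k / M_TO_UM
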