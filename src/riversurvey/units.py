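"""Unit constants and conversions.

Field protocol records distances in meters, effort in kilometers, and
densities in individuals per square kilometer.  Every conversion in the
package goes through this table so the m/km mixing of the density
formulas stays in one place.
"""

M_PER_KM = 1000.0


def m_to_km(meters: float) -> float:
    return meters / M_PER_KM


def km_to_m(km: float) -> float:
    return km * M_PER_KM
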