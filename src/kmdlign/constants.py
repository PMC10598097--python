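"""Pinned physical constants used throughout the package.

Monoisotopic masses of the lightest isotope of each supported element, in
unified atomic mass units (u), from the AME2020 atomic mass evaluation,
truncated to 8 decimal places. These are pinned here — not taken from a
third-party library at run time — so that every mass computed by the
package is reproducible to the last digit.
"""

from __future__ import annotations

#: Monoisotopic atomic masses (u). 12C defines the scale exactly.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "S": 31.97207117,
}

#: Mass of the proton (u); ESI (de)protonation shifts m/z by exactly this.
PROTON_MASS: float = 1.007276466

#: Elements handled by the formula machinery, in canonical Hill-ish order.
ELEMENT_ORDER: tuple[str, ...] = ("C", "H", "N", "O", "S")
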