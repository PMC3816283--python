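"""Perfusion-fluid composition and simple electrolyte arithmetic.

The in situ cardiac perfusion uses a bicarbonate-buffered physiological
saline. Total sodium is the sum over sodium-bearing species of
(millimolar concentration x sodium atoms per formula unit).
"""

from __future__ import annotations

import re
from typing import Mapping

__all__ = ["PERFUSION_BUFFER_MM", "sodium_atoms", "total_sodium_mm"]

#: Composition of the perfusion buffer, mM, keyed by chemical formula
#: (glucose written by name; it carries no sodium).
PERFUSION_BUFFER_MM: dict[str, float] = {
    "NaCl": 128.0,
    "NaHCO3": 24.0,
    "KCl": 4.2,
    "NaH2PO4": 2.4,
    "CaCl2": 1.5,
    "MgSO4": 0.9,
    "glucose": 9.0,
}

_NA = re.compile(r"Na(\d*)")


def sodium_atoms(formula: str) -> int:
    """Number of sodium atoms in a formula unit (e.g. 'Na2HPO4' -> 2)."""
    return sum(int(m or "1") for m in _NA.findall(formula))


def total_sodium_mm(composition: Mapping[str, float] | None = None) -> float:
    """Total [Na+] in mM contributed by all species of a buffer recipe.

    Parameters
    ----------
    composition : mapping of formula -> mM, optional
        Defaults to the perfusion buffer used for the uptake experiments.
    """
    if composition is None:
        composition = PERFUSION_BUFFER_MM
    for conc in composition.values():
        if conc < 0:
            raise ValueError("species concentrations must be non-negative")
    return float(sum(c * sodium_atoms(f) for f, c in composition.items()))
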