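"""Monoisotopic mass checks for synthesized tracer identity.

A high-resolution ESI-MS [M+H]+ value is the standard identity check for a
newly synthesized fluorescent hapten conjugate.  This module computes the
expected m/z from a molecular formula so the printed value can be verified.

Two conventions are supported, because publications are inconsistent about
whether the printed formula already contains the adduct hydrogen:

* neutral formula (default): m/z = monoisotopic(M) + 1.007276 (a proton);
* protonated composition: the printed formula is the ion's own atom list
  and the reported m/z is its plain monoisotopic atom sum (the adduct
  hydrogen counted as a neutral H atom, the electron mass neglected — the
  convention that reproduces typical HRMS tables to 4 decimals; the
  physically exact ion mass would be lower by one electron, 0.00055).
"""

from __future__ import annotations

import re
from typing import Mapping

from pyteomics import mass as _ptmass

from .errors import DomainError

__all__ = ["PROTON_MASS", "parse_formula", "monoisotopic_mass", "monoisotopic_mh"]

PROTON_MASS = 1.007276  # Da

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str | Mapping[str, int]) -> dict[str, int]:
    """Parse a Hill-notation formula string into element counts.

    ``"C58H69N6O12S3"`` -> ``{"C": 58, "H": 69, "N": 6, "O": 12, "S": 3}``.
    A mapping passes through (validated).
    """
    if isinstance(formula, Mapping):
        counts = {str(k): int(v) for k, v in formula.items()}
    else:
        s = formula.strip()
        if not s:
            raise DomainError("empty molecular formula")
        counts: dict[str, int] = {}
        pos = 0
        for m in _TOKEN.finditer(s):
            if m.start() != pos:
                raise DomainError(f"cannot parse formula {formula!r} at {s[pos:]!r}")
            counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
            pos = m.end()
        if pos != len(s):
            raise DomainError(f"cannot parse formula {formula!r} at {s[pos:]!r}")
    if not counts or all(v == 0 for v in counts.values()):
        raise DomainError("formula must contain at least one atom")
    if any(v < 0 for v in counts.values()):
        raise DomainError("element counts must be non-negative")
    for el in counts:
        if el not in _ptmass.nist_mass:
            raise DomainError(f"unknown element symbol {el!r}")
    return counts


def monoisotopic_mass(formula: str | Mapping[str, int]) -> float:
    """Monoisotopic (most-abundant-isotope) mass of a formula, in Da."""
    counts = parse_formula(formula)
    return float(_ptmass.calculate_mass(composition=counts))


def monoisotopic_mh(
    formula: str | Mapping[str, int],
    protonated_composition: bool = False,
) -> float:
    """[M+H]+ m/z for a molecular formula, reported to 4 decimals.

    With ``protonated_composition=False`` (default) the formula is the
    neutral molecule M and a proton mass is added.  With True the formula is
    taken as the protonated ion's own composition and its plain atom sum is
    returned (see module docstring for why both exist).
    """
    m = monoisotopic_mass(formula)
    if protonated_composition:
        return round(m, 4)
    return round(m + PROTON_MASS, 4)
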