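"""Elemental formulas with possibly non-integer stoichiometric counts.

Biomass pseudo-species are conventionally written per carbon with fractional
subscripts (e.g. CH1.9O0.5N0.2), so counts are non-negative reals rather
than integers.
"""

from __future__ import annotations

import re
from collections.abc import Mapping
from dataclasses import dataclass, field

#: Element symbols permitted in this package.
ALLOWED_ELEMENTS = ("C", "H", "O", "N", "P", "S")

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d+\.?\d*|\.\d+)?")


@dataclass(frozen=True)
class ElementalFormula:
    """Mapping of element symbol to a non-negative stoichiometric count.

    Parameters
    ----------
    composition
        Element → count. Counts must be non-negative and at least one must
        be positive. Elements are restricted to C, H, O, N, P, S.
    """

    composition: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        comp = {e: float(n) for e, n in self.composition.items() if float(n) != 0.0}
        if not comp:
            raise ValueError("formula must contain at least one element")
        for element, count in comp.items():
            if element not in ALLOWED_ELEMENTS:
                raise ValueError(
                    f"unsupported element {element!r}; allowed: {ALLOWED_ELEMENTS}"
                )
            if count < 0:
                raise ValueError(f"negative count for element {element!r}")
        object.__setattr__(self, "composition", comp)

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse a Hill-style formula string such as ``C3H8O3`` or ``CH1.9O0.5N0.2``."""
        if not text or not text.strip():
            raise ValueError("empty formula string")
        pos = 0
        comp: dict[str, float] = {}
        for match in _TOKEN.finditer(text.strip()):
            if match.start() != pos:
                raise ValueError(f"cannot parse formula {text!r} at offset {pos}")
            pos = match.end()
            element = match.group(1)
            count = float(match.group(2)) if match.group(2) else 1.0
            comp[element] = comp.get(element, 0.0) + count
        if pos != len(text.strip()):
            raise ValueError(f"cannot parse formula {text!r} at offset {pos}")
        return cls(comp)

    def count(self, element: str) -> float:
        return self.composition.get(element, 0.0)

    def __str__(self) -> str:
        parts = []
        for element in ALLOWED_ELEMENTS:
            n = self.composition.get(element, 0.0)
            if n == 0.0:
                continue
            if n == 1.0:
                parts.append(element)
            elif n == int(n):
                parts.append(f"{element}{int(n)}")
            else:
                parts.append(f"{element}{n:g}")
        return "".join(parts)


def as_formula(value: "ElementalFormula | Mapping[str, float] | str") -> ElementalFormula:
    """Coerce a string, mapping or ElementalFormula into an ElementalFormula."""
    if isinstance(value, ElementalFormula):
        return value
    if isinstance(value, str):
        return ElementalFormula.parse(value)
    return ElementalFormula(dict(value))
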