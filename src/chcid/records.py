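"""Compound-table records and nominal-mass arithmetic."""

from __future__ import annotations

from dataclasses import dataclass, field

from pyteomics import mass as _pmass

from .errors import FormulaError

# Integer (nominal) element masses for the CxHyOz formulas the table holds.
_NOMINAL = {"C": 12, "H": 1, "O": 16}


def nominal_mass(formula: str) -> int:
    """Nominal (integer) mass of a CxHyOz formula: C=12, H=1, O=16."""
    try:
        comp = _pmass.Composition(formula=formula.strip())
    except Exception as exc:  # pyteomics raises its own error type
        raise FormulaError(f"cannot parse formula {formula!r}") from exc
    if not comp:
        raise FormulaError(f"empty formula {formula!r}")
    unknown = set(comp) - set(_NOMINAL)
    if unknown:
        raise FormulaError(
            f"formula {formula!r} contains elements outside C/H/O: {sorted(unknown)}"
        )
    return sum(_NOMINAL[el] * n for el, n in comp.items())


def alkane_formula(carbons: int, unsaturation: int = 0) -> str:
    """CnH(2n+2-2u) formula string for an acyclic hydrocarbon."""
    h = 2 * carbons + 2 - 2 * unsaturation
    return f"C{carbons}H{h}"


@dataclass(frozen=True)
class CompoundRecord:
    """One output row: the identification of a single chromatographic peak."""

    retention_time: float  # minutes
    nominal_mw: int | None  # Da
    molecular_formula: str | None
    structure_name: str
    ri: int | None
    peak_id: str = ""
    flags: frozenset[str] = field(default_factory=frozenset)
    annotation: str = ""

    def with_flags(self, *more: str) -> "CompoundRecord":
        from dataclasses import replace

        return replace(self, flags=self.flags | frozenset(more))
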