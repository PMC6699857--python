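"""IUPAC-style names for linear and methyl-branched alkanes.

Covers parent chains up to C40 and up to five methyl substituents, which is
the range cuticular-hydrocarbon work needs.  Ambiguous branch positions are
rendered with the conventional leading ``*-`` (e.g. ``*-dimethyloctacosane``).
"""

from __future__ import annotations

import re

from .errors import UnsupportedStructureError

ALKANE_NAMES: dict[int, str] = {
    1: "methane", 2: "ethane", 3: "propane", 4: "butane", 5: "pentane",
    6: "hexane", 7: "heptane", 8: "octane", 9: "nonane", 10: "decane",
    11: "undecane", 12: "dodecane", 13: "tridecane", 14: "tetradecane",
    15: "pentadecane", 16: "hexadecane", 17: "heptadecane", 18: "octadecane",
    19: "nonadecane", 20: "eicosane", 21: "heneicosane", 22: "docosane",
    23: "tricosane", 24: "tetracosane", 25: "pentacosane", 26: "hexacosane",
    27: "heptacosane", 28: "octacosane", 29: "nonacosane", 30: "triacontane",
    31: "hentriacontane", 32: "dotriacontane", 33: "tritriacontane",
    34: "tetratriacontane", 35: "pentatriacontane", 36: "hexatriacontane",
    37: "heptatriacontane", 38: "octatriacontane", 39: "nonatriacontane",
    40: "tetracontane",
}

_NAME_TO_CARBONS = {v: k for k, v in ALKANE_NAMES.items()}

MULTIPLIERS = {1: "methyl", 2: "dimethyl", 3: "trimethyl", 4: "tetramethyl", 5: "pentamethyl"}
_MULTIPLIER_TO_COUNT = {v: k for k, v in MULTIPLIERS.items()}


def alkane_name(carbons: int) -> str:
    try:
        return ALKANE_NAMES[carbons]
    except KeyError:
        raise UnsupportedStructureError(f"no alkane name for C{carbons}") from None


def alkene_name(carbons: int) -> str:
    """Name of the monoene with unplaced double bond, e.g. ``*-tricosene``."""
    stem = alkane_name(carbons)[:-3]  # strip "ane"
    return f"*-{stem}ene"


def branched_name(chain: int, locants: tuple[int, ...], ambiguous: bool = False) -> str:
    """``9-methylnonacosane`` / ``5,9-dimethylnonacosane`` / ``*-dimethyl...``."""
    if not locants:
        return alkane_name(chain).capitalize()
    if len(locants) not in MULTIPLIERS:
        raise UnsupportedStructureError(
            f"{len(locants)} methyl branches exceed the penta multiplier"
        )
    prefix = MULTIPLIERS[len(locants)]
    stem = alkane_name(chain)
    if ambiguous:
        return f"*-{prefix}{stem}"
    return f"{','.join(str(p) for p in locants)}-{prefix}{stem}"


_BRANCHED_RE = re.compile(
    r"^(?P<locants>\*|\d+(?:,\d+)*)-(?P<mult>methyl|dimethyl|trimethyl|tetramethyl|pentamethyl)"
    r"(?P<stem>[a-z]+ane)$"
)


def parse_name(name: str) -> tuple[int, tuple[int, ...]]:
    """Parse an alkane name back to (parent_chain_length, locants).

    Only fully specified saturated names are parseable; ``*-`` names raise
    because the locants are unknown.
    """
    text = name.strip().lower()
    if text in _NAME_TO_CARBONS:
        return _NAME_TO_CARBONS[text], ()
    m = _BRANCHED_RE.match(text)
    if not m:
        raise ValueError(f"cannot parse alkane name {name!r}")
    if m.group("locants") == "*":
        raise ValueError(f"ambiguous name {name!r} has no defined locants")
    stem = m.group("stem")
    if stem not in _NAME_TO_CARBONS:
        raise ValueError(f"unknown parent alkane {stem!r} in {name!r}")
    locants = tuple(sorted(int(x) for x in m.group("locants").split(",")))
    if len(locants) != _MULTIPLIER_TO_COUNT[m.group("mult")]:
        raise ValueError(f"locant count does not match multiplier in {name!r}")
    return _NAME_TO_CARBONS[stem], locants
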