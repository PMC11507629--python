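"""Secondary-structure label alphabets and the 8-state to 3-state reduction.

Two alphabets are used throughout the package:

* ``SS8`` — the eight DSSP states H (alpha-helix), T (turn), S (bend),
  I (pi-helix), G (3-10 helix), E (beta-strand), B (beta-bridge) and
  C (other/irregular).
* ``SS3`` — the coarse three-state scheme H (helix), E (sheet), C (coil).

State order within each alphabet is fixed so that integer indices are a
stable bijection with symbols (index 0 is 'H' in both alphabets).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping


@dataclass(frozen=True)
class LabelAlphabet:
    """An ordered secondary-structure state alphabet.

    Parameters
    ----------
    name:
        Short identifier, ``"SS8"`` or ``"SS3"`` for the built-ins.
    states:
        State symbols in index order; ``index(sym)`` and ``symbol(i)``
        convert between the two representations.
    """

    name: str
    states: str

    def __post_init__(self) -> None:
        if len(set(self.states)) != len(self.states):
            raise ValueError(f"duplicate states in alphabet {self.name!r}")

    @property
    def size(self) -> int:
        return len(self.states)

    def index(self, symbol: str) -> int:
        i = self.states.find(symbol)
        if i < 0:
            raise KeyError(f"symbol {symbol!r} not in alphabet {self.name}")
        return i

    def symbol(self, index: int) -> str:
        return self.states[index]

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.states


#: Eight-state alphabet. Order: helices first (H, G, I), then strands (E, B),
#: then the coil-like states (T, S, C); chosen so the SS3 reduction maps
#: contiguous index blocks.
SS8 = LabelAlphabet("SS8", "HGIEBTSC")

#: Three-state alphabet: helix, sheet, coil.
SS3 = LabelAlphabet("SS3", "HEC")

#: Conventional DSSP coarse-graining: 3-10, alpha and pi helices collapse to
#: helix; strand and bridge to sheet; turn, bend and irregular to coil.
DEFAULT_8_TO_3: Mapping[str, str] = {
    "H": "H", "G": "H", "I": "H",
    "E": "E", "B": "E",
    "T": "C", "S": "C", "C": "C",
}


def get_alphabet(name: str) -> LabelAlphabet:
    """Look up a built-in alphabet by name (case-insensitive)."""
    key = name.upper()
    if key == "SS8":
        return SS8
    if key == "SS3":
        return SS3
    raise KeyError(f"unknown alphabet {name!r}; expected 'SS8' or 'SS3'")
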