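"""Sequence alphabet: 20 amino acids plus the gap state.

The gap is a first-class state everywhere (frequency counting, energy
evaluation, Monte Carlo proposals), so q = 21.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"

#: Non-standard residue codes collapsed onto the gap state on input.
NON_STANDARD = frozenset("BZXUOJ*.")


@dataclass(frozen=True)
class Alphabet:
    """Ordered 21-letter alphabet with a bijective symbol <-> index map."""

    symbols: str = AMINO_ACIDS + GAP
    _index: dict = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if len(self.symbols) != len(set(self.symbols)):
            raise ValueError("alphabet symbols must be unique")
        if GAP not in self.symbols:
            raise ValueError("alphabet must contain the gap symbol '-'")
        object.__setattr__(
            self, "_index", {s: i for i, s in enumerate(self.symbols)}
        )

    @property
    def q(self) -> int:
        return len(self.symbols)

    @property
    def gap_index(self) -> int:
        return self._index[GAP]

    def index(self, symbol: str) -> int:
        try:
            return self._index[symbol]
        except KeyError:
            raise ValidationError(f"symbol {symbol!r} not in alphabet") from None

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._index

    def encode(self, sequence: str) -> np.ndarray:
        """Encode a sequence to int8 indices. Raises on unknown symbols."""
        try:
            return np.fromiter(
                (self._index[s] for s in sequence), dtype=np.int8, count=len(sequence)
            )
        except KeyError as exc:
            raise ValidationError(f"symbol {exc.args[0]!r} not in alphabet") from None

    def decode(self, indices) -> str:
        return "".join(self.symbols[int(i)] for i in indices)


#: Module-level default: 20 amino acids in alphabetical one-letter order, gap last.
PROTEIN = Alphabet()
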