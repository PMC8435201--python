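"""Character-state alphabets for alignments and substitution models.

An :class:`Alphabet` declares the ordered set of unambiguous states, the
gap symbol, and the fully-ambiguous ("missing") symbols.  Gap and missing
symbols are treated identically by the likelihood machinery: a partial
likelihood of 1 for every state.  The amino-acid state order is the PAML
convention (ARNDCQEGHILKMFPSTWYV), matching the embedded empirical
exchangeability matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Alphabet:
    name: str
    states: str
    gap: str = "-"
    missing: frozenset[str] = field(default_factory=frozenset)

    @property
    def k(self) -> int:
        return len(self.states)

    @property
    def ambiguous(self) -> frozenset[str]:
        """All symbols contributing likelihood 1 for every state."""
        return self.missing | {self.gap}

    def is_valid_symbol(self, symbol: str) -> bool:
        return symbol in self.states or symbol in self.ambiguous

    def index(self, symbol: str) -> int:
        """State index of an unambiguous symbol, or -1 for gap/missing."""
        if symbol in self.ambiguous:
            return -1
        return self.states.index(symbol)


AMINO_ACID = Alphabet(
    name="amino-acid",
    states="ARNDCQEGHILKMFPSTWYV",
    missing=frozenset({"X", "?"}),
)

NUCLEOTIDE = Alphabet(
    name="nucleotide",
    states="ACGT",
    missing=frozenset({"N", "?"}),
)

BINARY = Alphabet(name="binary", states="01", missing=frozenset({"?"}))


def generic_alphabet(k: int) -> Alphabet:
    """A k-state alphabet over digits/letters, for tests and toy models."""
    symbols = "0123456789ABCDEFGHIJ"
    if not 2 <= k <= len(symbols):
        raise ValueError(f"generic alphabet supports 2..{len(symbols)} states, got {k}")
    return Alphabet(name=f"generic-{k}", states=symbols[:k], missing=frozenset({"?"}))
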