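"""Amino-acid token alphabet.

Uses the 33-token layout shared by the ESM model family (cls/pad/eos/unk,
the 20 canonical amino acids, the rare codes X/B/U/Z/O, "." and "-", a null
placeholder, and the mask token) so that checkpoints trained with that
vocabulary remain loadable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["TokenAlphabet", "CANONICAL_AA", "esm_alphabet"]

CANONICAL_AA = "LAGVSERTIDPKQNFYMHWC"
_RARE_AA = "XBUZO"

_ESM_TOKENS = (
    ["<cls>", "<pad>", "<eos>", "<unk>"]
    + list(CANONICAL_AA)
    + list(_RARE_AA)
    + [".", "-", "<null_1>", "<mask>"]
)


@dataclass(frozen=True)
class TokenAlphabet:
    """Ordered token vocabulary with special-token bookkeeping.

    Invariants: ids are the positions in ``tokens`` (unique, in
    ``[0, vocab_size)``); every canonical amino acid maps to exactly one id;
    ``decode(encode(s)) == s`` for canonical sequences.
    """

    tokens: tuple[str, ...]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("duplicate tokens in alphabet")
        for aa in CANONICAL_AA:
            if aa not in self.tokens:
                raise ValueError(f"canonical amino acid {aa!r} missing from alphabet")
        object.__setattr__(self, "_index", {t: i for i, t in enumerate(self.tokens)})

    @property
    def vocab_size(self) -> int:
        return len(self.tokens)

    @property
    def cls_id(self) -> int:
        return self._index["<cls>"]

    @property
    def pad_id(self) -> int:
        return self._index["<pad>"]

    @property
    def eos_id(self) -> int:
        return self._index["<eos>"]

    @property
    def unk_id(self) -> int:
        return self._index["<unk>"]

    @property
    def mask_id(self) -> int:
        return self._index["<mask>"]

    @property
    def residue_ids(self) -> tuple[int, ...]:
        """Ids of the 20 canonical amino acids."""
        return tuple(self._index[aa] for aa in CANONICAL_AA)

    def id_of(self, token: str) -> int:
        return self._index[token]

    def encode(self, sequence: str) -> list[int]:
        """Tokenize one amino-acid sequence as [cls] + residues + [eos].

        Lowercase residues are accepted and uppercased. Non-letter characters
        and empty sequences are errors; letters outside the alphabet map to
        the unk token.
        """
        if not sequence:
            raise ValueError("cannot tokenize an empty sequence")
        ids = [self.cls_id]
        for pos, ch in enumerate(sequence):
            if not ch.isalpha():
                raise ValueError(
                    f"non-letter character {ch!r} at position {pos + 1} in sequence")
            ids.append(self._index.get(ch.upper(), self.unk_id))
        ids.append(self.eos_id)
        return ids

    def decode(self, ids) -> str:
        """Inverse of :meth:`encode` including the special tokens."""
        return "".join(self.tokens[int(i)] for i in ids)

    def decode_residues(self, ids) -> str:
        """Decode dropping a leading cls and trailing eos if present."""
        ids = list(ids)
        if ids and ids[0] == self.cls_id:
            ids = ids[1:]
        if ids and ids[-1] == self.eos_id:
            ids = ids[:-1]
        return self.decode(ids)


def esm_alphabet() -> TokenAlphabet:
    """The standard 33-token alphabet."""
    return TokenAlphabet(tuple(_ESM_TOKENS))


def tokenize(sequence: str, alphabet: TokenAlphabet | None = None) -> list[int]:
    """Module-level convenience wrapper around :meth:`TokenAlphabet.encode`."""
    return (alphabet or esm_alphabet()).encode(sequence)
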