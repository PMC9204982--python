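"""Sequence/SMILES encoding and label transformation.

Interaction records carry a dissociation constant Kd in nanomolar, which is
mapped to the log-scale regression target pKd = -log10(Kd / 1e9).  Protein
sequences and SMILES strings are tokenized through data-derived character
dictionaries and expanded to padded one-hot matrices; index 0 is reserved
for padding and its one-hot row is all-zero, so padded positions contribute
nothing to downstream convolutions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "InteractionRecord",
    "TokenDictionary",
    "EncodedInput",
    "kd_to_pkd",
    "build_dictionary",
    "encode_and_pad",
    "filter_records",
    "canonicalize_smiles",
    "CANONICAL_AMINO_ACIDS",
]

#: The 20 canonical amino acids, sorted alphabetically.
CANONICAL_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def kd_to_pkd(kd_nM: float) -> float:
    """Transform a dissociation constant (nM) into log-space pKd.

    pKd = -log10(Kd / 1e9), i.e. the negative decimal log of Kd in molar.
    A weak interaction of 10,000 nM maps to pKd = 5.

    Raises
    ------
    ValueError
        If ``kd_nM`` is non-positive or non-finite.
    """
    kd = float(kd_nM)
    if not math.isfinite(kd) or kd <= 0.0:
        raise ValueError(f"Kd must be a positive finite value in nM, got {kd_nM!r}")
    return -math.log10(kd / 1e9)


def pkd_to_kd(pkd: float) -> float:
    """Inverse of :func:`kd_to_pkd`: Kd in nM from pKd."""
    return 10.0 ** (9.0 - float(pkd))


@dataclass
class InteractionRecord:
    """One protein-compound pair with its binding-affinity label."""

    protein_id: str
    protein_seq: str
    compound_id: str
    smiles: str
    kd_nM: float
    pkd: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.pkd is None:
            self.pkd = kd_to_pkd(self.kd_nM)


@dataclass(frozen=True)
class TokenDictionary:
    """Injective single-character -> integer mapping with indices 1..size.

    Index 0 is reserved for padding and maps to no symbol.
    """

    symbol_to_index: dict[str, int]

    @property
    def size(self) -> int:
        return len(self.symbol_to_index)

    def __post_init__(self) -> None:
        idx = sorted(self.symbol_to_index.values())
        if idx != list(range(1, len(idx) + 1)):
            raise ValueError("dictionary indices must be consecutive 1..size")

    def index_of(self, symbol: str) -> int:
        return self.symbol_to_index[symbol]

    @property
    def index_to_symbol(self) -> dict[int, str]:
        return {i: s for s, i in self.symbol_to_index.items()}


@dataclass(frozen=True)
class EncodedInput:
    """Padded token vector, one-hot matrix and validity mask for one sequence."""

    tokens: np.ndarray  # (L_max,) int
    onehot: np.ndarray  # (L_max, dict_size) float
    mask: np.ndarray  # (L_max,) int, 1 = real position


def build_dictionary(sequences: Iterable[str]) -> TokenDictionary:
    """Build a token dictionary from the distinct characters of ``sequences``.

    Indices are assigned in sorted-symbol order starting at 1, so the mapping
    is deterministic across runs and platforms.
    """
    seqs = list(sequences)
    if not seqs:
        raise ValueError("cannot build a dictionary from an empty sequence list")
    symbols = sorted(set().union(*[set(s) for s in seqs]))
    if not symbols:
        raise ValueError("sequences contain no characters")
    return TokenDictionary({s: i + 1 for i, s in enumerate(symbols)})


def encode_and_pad(seq: str, dictionary: TokenDictionary, l_max: int) -> EncodedInput:
    """Encode ``seq`` to integer tokens, zero-pad to ``l_max`` and one-hot expand.

    The one-hot matrix has one column per dictionary index 1..size; padded
    positions (token 0) expand to all-zero rows.
    """
    if len(seq) > l_max:
        raise ValueError(f"sequence of length {len(seq)} exceeds maximum {l_max}")
    tokens = np.zeros(l_max, dtype=np.int64)
    for pos, ch in enumerate(seq):
        try:
            tokens[pos] = dictionary.symbol_to_index[ch]
        except KeyError:
            raise KeyError(
                f"unknown character {ch!r} at position {pos + 1} "
                f"(dictionary has {dictionary.size} symbols)"
            ) from None
    onehot = np.zeros((l_max, dictionary.size), dtype=np.float32)
    real = tokens > 0
    onehot[np.nonzero(real)[0], tokens[real] - 1] = 1.0
    mask = real.astype(np.int64)
    return EncodedInput(tokens=tokens, onehot=onehot, mask=mask)


def filter_records(
    records: Sequence[InteractionRecord],
    prot_len: tuple[int, int],
    smiles_len: tuple[int, int],
) -> list[InteractionRecord]:
    """Keep records whose protein and SMILES lengths lie in the closed bounds.

    The length windows follow the dataset curation that keeps proteins of
    264-1400 residues and SMILES of 38-72 characters; bounds are inclusive.
    Order is preserved and the operation is idempotent.
    """
    for lo, hi in (prot_len, smiles_len):
        if lo <= 0 or hi <= 0 or lo > hi:
            raise ValueError(f"invalid length bounds ({lo}, {hi})")
    out = []
    for r in records:
        if prot_len[0] <= len(r.protein_seq) <= prot_len[1] and (
            smiles_len[0] <= len(r.smiles) <= smiles_len[1]
        ):
            out.append(r)
    return out


def canonicalize_smiles(smiles: str) -> str:
    """Return the RDKit canonical SMILES for ``smiles``.

    Canonicalization is idempotent and maps any two spellings of the same
    molecular graph to one string.  The canonical form is toolkit-dependent;
    :func:`toolkit_version` reports the RDKit release for output metadata.
    """
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles, sanitize=True)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def toolkit_version() -> str:
    """RDKit version string, recorded in run manifests."""
    import rdkit

    return rdkit.__version__
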