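"""Protein and compound similarity used by the representative splitter.

Protein similarity is the Smith-Waterman local-alignment score under BLOSUM62
with affine gap penalties (opening 10, extension 0.5), normalized to [0,1]
by dividing the raw score by the geometric mean of the two self-alignment
scores:

    SW_norm(p1, p2) = SW(p1, p2) / (sqrt(SW(p1, p1)) * sqrt(SW(p2, p2)))

Compound similarity is the Tanimoto coefficient between Morgan circular
fingerprints of radius 3.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SimilarityMatrix",
    "Fingerprint",
    "load_substitution_matrix",
    "blosum62",
    "smith_waterman",
    "normalize_sw",
    "normalized_sw_similarity",
    "morgan_fingerprint",
    "tanimoto",
    "similarity_matrix",
]

DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric entity-by-entity similarity with unit diagonal."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("values must be square with one row per id")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate ids in similarity matrix")

    def lookup(self, id_a: str, id_b: str) -> float:
        ia = self.ids.index(id_a)
        ib = self.ids.index(id_b)
        return float(self.values[ia, ib])

    def indexer(self) -> dict[str, int]:
        return {e: i for i, e in enumerate(self.ids)}

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids)).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "SimilarityMatrix":
        import pandas as pd

        df = pd.read_csv(path, index_col=0)
        return cls(ids=tuple(str(c) for c in df.columns), values=df.to_numpy(dtype=float))


@dataclass(frozen=True)
class Fingerprint:
    """Set-of-on-bits view of a binary molecular fingerprint."""

    on_bits: frozenset[int]
    nbits: int

    def __post_init__(self) -> None:
        if any(b < 0 or b >= self.nbits for b in self.on_bits):
            raise ValueError("bit index outside [0, nbits)")


def load_substitution_matrix(path=None):
    """Load a substitution matrix from NCBI flat text (default: bundled BLOSUM62)."""
    from Bio.Align import substitution_matrices

    if path is None:
        ref = importlib.resources.files("xdta.data").joinpath("BLOSUM62.txt")
        with importlib.resources.as_file(ref) as p:
            return substitution_matrices.read(str(p))
    return substitution_matrices.read(str(path))


_BLOSUM62_CACHE = None


def blosum62():
    """The bundled BLOSUM62 matrix (cached)."""
    global _BLOSUM62_CACHE
    if _BLOSUM62_CACHE is None:
        _BLOSUM62_CACHE = load_substitution_matrix()
    return _BLOSUM62_CACHE


def smith_waterman(
    p1: str,
    p2: str,
    submat=None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> float:
    """Optimal local-alignment score with affine gap penalties.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``: the first
    gapped position pays the opening penalty, each further position the
    extension penalty.  Returns 0 when no positive-scoring local alignment
    exists (e.g. one sequence empty).

    Parameters
    ----------
    submat
        A Biopython substitution matrix (default: bundled BLOSUM62).
    """
    if submat is None:
        submat = blosum62()
    if gap_extend < 0 or gap_open < gap_extend:
        raise ValueError("require gap_open >= gap_extend >= 0")
    n, m = len(p1), len(p2)
    if n == 0 or m == 0:
        return 0.0

    alpha = {c: i for i, c in enumerate(submat.alphabet)}
    try:
        a = [alpha[c] for c in p1]
        b = [alpha[c] for c in p2]
    except KeyError as exc:
        raise KeyError(f"symbol {exc.args[0]!r} missing from substitution matrix") from None
    S = np.asarray(submat, dtype=float)

    neg_inf = float("-inf")
    # Two-row DP over three states: H (match), E (gap in p1), F (gap in p2).
    h_prev = [0.0] * (m + 1)
    f_prev = [neg_inf] * (m + 1)
    best = 0.0
    for i in range(1, n + 1):
        srow = S[a[i - 1]]
        h_cur = [0.0] * (m + 1)
        f_cur = [neg_inf] * (m + 1)
        e = neg_inf
        for j in range(1, m + 1):
            e = max(h_cur[j - 1] - gap_open, e - gap_extend)
            f = max(h_prev[j] - gap_open, f_prev[j] - gap_extend)
            h = max(0.0, h_prev[j - 1] + srow[b[j - 1]], e, f)
            h_cur[j] = h
            f_cur[j] = f
            if h > best:
                best = h
        h_prev, f_prev = h_cur, f_cur
    return best


def normalize_sw(raw: float, self1: float, self2: float) -> float:
    """Normalize a raw alignment score by the two self-alignment scores."""
    if self1 <= 0 or self2 <= 0:
        raise ValueError("self-alignment scores must be positive (degenerate sequence)")
    # sqrt(a)*sqrt(b) computed as sqrt(a*b): identical value, and exact 1.0
    # for self-pairs (s / sqrt(s^2) = 1).
    return float(raw) / float(np.sqrt(float(self1) * float(self2)))


def normalized_sw_similarity(
    p1: str,
    p2: str,
    submat=None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> float:
    """Normalized Smith-Waterman similarity of two sequences in [0,1]."""
    raw = smith_waterman(p1, p2, submat, gap_open, gap_extend)
    s1 = smith_waterman(p1, p1, submat, gap_open, gap_extend)
    s2 = smith_waterman(p2, p2, submat, gap_open, gap_extend)
    return normalize_sw(raw, s1, s2)


def morgan_fingerprint(smiles: str, radius: int = 3, nbits: int = 2048) -> Fingerprint:
    """Morgan circular fingerprint (presence/absence bits) of a SMILES string."""
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    if radius < 0:
        raise ValueError("radius must be >= 0")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
    bv = gen.GetFingerprint(mol)
    return Fingerprint(on_bits=frozenset(bv.GetOnBits()), nbits=nbits)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |a&b| / |a|b|; 0 when both fingerprints are empty."""
    if a.nbits != b.nbits:
        raise ValueError(f"fingerprint length mismatch: {a.nbits} vs {b.nbits}")
    union = len(a.on_bits | b.on_bits)
    if union == 0:
        return 0.0
    return len(a.on_bits & b.on_bits) / union


def similarity_matrix(
    ids: Sequence[str],
    entities: Sequence,
    pairwise_fn: Callable,
) -> SimilarityMatrix:
    """Fill a symmetric similarity matrix, one ``pairwise_fn`` call per pair.

    The diagonal is forced to exactly 1.
    """
    if len(ids) == 0:
        raise ValueError("no entities")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids")
    if len(ids) != len(entities):
        raise ValueError("ids and entities length mismatch")
    n = len(ids)
    values = np.eye(n, dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            v = float(pairwise_fn(entities[i], entities[j]))
            values[i, j] = values[j, i] = v
    return SimilarityMatrix(ids=tuple(ids), values=values)


def protein_similarity_matrix(ids, sequences, submat=None) -> SimilarityMatrix:
    """Normalized Smith-Waterman similarity over a protein panel.

    Self-alignment scores are computed once per sequence.
    """
    if submat is None:
        submat = blosum62()
    selfs = [smith_waterman(s, s, submat) for s in sequences]
    for i, sc in enumerate(selfs):
        if sc <= 0:
            raise ValueError(f"degenerate sequence {ids[i]!r}: nonpositive self-score")
    idx = {id(seq): k for k, seq in enumerate(sequences)}

    def fn(s1, s2):
        return normalize_sw(
            smith_waterman(s1, s2, submat), selfs[idx[id(s1)]], selfs[idx[id(s2)]]
        )

    return similarity_matrix(ids, sequences, fn)


def compound_similarity_matrix(ids, smiles_list, radius: int = 3, nbits: int = 2048,
                               strict: bool = True) -> SimilarityMatrix:
    """Tanimoto/Morgan similarity over a compound panel.

    With ``strict=False``, unparseable SMILES (e.g. synthetic placeholder
    strings) fall back to a character 3-gram Jaccard similarity so that the
    splitter remains usable on simulated data.
    """
    fps: list = []
    for sid, smi in zip(ids, smiles_list):
        try:
            fps.append(morgan_fingerprint(smi, radius=radius, nbits=nbits))
        except ValueError:
            if strict:
                raise
            fps.append(None)
    grams = [frozenset(s[i : i + 3] for i in range(max(1, len(s) - 2))) for s in smiles_list]

    def fn_idx(i, j):
        if fps[i] is not None and fps[j] is not None:
            return tanimoto(fps[i], fps[j])
        union = grams[i] | grams[j]
        return len(grams[i] & grams[j]) / len(union) if union else 0.0

    n = len(ids)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = fn_idx(i, j)
    return SimilarityMatrix(ids=tuple(ids), values=values)
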