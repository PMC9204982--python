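"""Window-based pockets and localization-map evaluation statistics.

Annotated binding sites (or conserved PSSM motifs) are sparse single residue
positions.  Around each site p a pocket of window size s_w spans the
positions q with |q - p| <= s_w, clipped to the sequence and truncated at
the midpoint between consecutive sites so pockets never overlap and never
contain another site (the midpoint position goes to the lower pocket).

Two statistics quantify whether a localization map attends to the pockets:

* matching — the weighted average over pairs of the fraction of a pair's
  pockets holding at least one strictly positive map value; with weights
  B_p / sum(B_p) this pools to  100 * (#pockets with a hit) / (#pockets).
* feature relevance — the weighted average of the fraction of pocket
  positive values that fall into the top-lambda set of the pair's positive
  values, pooling to  100 * (#qualifying pocket values) / (#pocket positive
  values).  The top-lambda set holds the floor(lambda * n_pos) largest
  positive values, with boundary ties included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .gradram import LocalizationMap

__all__ = ["AnnotatedSites", "PocketSet", "PSSMProfile", "build_pockets",
           "matching", "feature_relevance", "parse_pssm",
           "pssm_motif_positions", "filter_motifs_outside_binding_region",
           "DEFAULT_WINDOW_GRID", "DEFAULT_LAMBDA_GRID"]

#: Window sizes evaluated by default, 0 = exact site matching.
DEFAULT_WINDOW_GRID = (0, 1, 2, 3, 4, 5)
#: Relevance thresholds: top 10% .. top 70% of positive-valued features.
DEFAULT_LAMBDA_GRID = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7)

# PSI-BLAST PSSM column order.
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"


@dataclass(frozen=True)
class AnnotatedSites:
    """Sparse 1-based annotated positions (binding sites or motifs) of a pair."""

    pair_id: str
    positions: tuple[int, ...]
    kind: str = "binding"  # "binding" | "motif"

    def __post_init__(self) -> None:
        pos = self.positions
        if any(p <= 0 for p in pos):
            raise ValueError("positions are 1-based and must be positive")
        if any(pos[i] >= pos[i + 1] for i in range(len(pos) - 1)):
            raise ValueError("positions must be strictly increasing")


@dataclass(frozen=True)
class PocketSet:
    """Disjoint closed intervals around annotated sites."""

    pockets: tuple[tuple[int, int, int], ...]  # (site, lo, hi), 1-based closed
    s_w: int


@dataclass(frozen=True)
class PSSMProfile:
    """Per-position substitution scores from a PSI-BLAST profile."""

    scores: np.ndarray  # (length, 20)
    consensus: str  # the query sequence of the profile

    def __post_init__(self) -> None:
        if self.scores.shape != (len(self.consensus), 20):
            raise ValueError("scores must be length x 20")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("non-finite PSSM scores")

    @property
    def length(self) -> int:
        return len(self.consensus)


def build_pockets(sites: AnnotatedSites, s_w: int, seq_len: int,
                  strict_open: bool = False) -> PocketSet:
    """Window-based pockets of half-width ``s_w`` around each annotated site.

    Closed intervals by default, so s_w = 0 is exact matching on the site
    itself; ``strict_open`` instead uses the open interval ]p-s_w, p+s_w[
    (empty at s_w = 0).  Consecutive pockets are truncated at the midpoint
    between their sites, the midpoint going to the lower pocket.
    """
    if s_w < 0:
        raise ValueError("window size must be >= 0")
    pos = sites.positions
    if any(p > seq_len for p in pos):
        raise ValueError(f"site beyond sequence length {seq_len}")
    half = s_w - 1 if strict_open else s_w
    pockets = []
    for i, p in enumerate(pos):
        if half < 0:
            continue  # strict open interval with s_w = 0 is empty
        lo = max(1, p - half)
        hi = min(seq_len, p + half)
        if i > 0:
            mid = (pos[i - 1] + p) // 2
            lo = max(lo, mid + 1)
        if i + 1 < len(pos):
            mid = (p + pos[i + 1]) // 2
            hi = min(hi, mid)
        pockets.append((p, lo, hi))
    return PocketSet(pockets=tuple(pockets), s_w=s_w)


def _pocket_values(map_values: np.ndarray, pocket: tuple[int, int, int]) -> np.ndarray:
    _, lo, hi = pocket
    return map_values[lo - 1 : hi]  # 1-based closed -> 0-based half-open


def matching(maps: Sequence[LocalizationMap],
             pockets_per_pair: Sequence[PocketSet]) -> float:
    """Percentage of pockets holding at least one strictly positive map value."""
    if len(maps) != len(pockets_per_pair):
        raise ValueError("one pocket set per map required")
    total = hits = 0
    for loc, ps in zip(maps, pockets_per_pair):
        if not ps.pockets:
            raise ValueError("pair with empty pocket set")
        for pocket in ps.pockets:
            total += 1
            if np.any(_pocket_values(loc.values, pocket) > 0):
                hits += 1
    return 100.0 * hits / total


def _top_lambda_threshold(positives: np.ndarray, lam: float) -> float | None:
    """Value of the k-th largest positive, k = floor(lam * n); None if k = 0."""
    k = int(np.floor(lam * positives.size))
    if k <= 0:
        return None
    return float(np.sort(positives)[::-1][k - 1])


def feature_relevance(maps: Sequence[LocalizationMap],
                      pockets_per_pair: Sequence[PocketSet], lam: float) -> float:
    """Percentage of pocket positive values inside each pair's top-lambda set.

    The top-lambda set of a pair consists of the floor(lambda * n_pos)
    largest strictly positive map values (ties at the boundary included).
    Pairs without positive pocket values contribute nothing; if no pair has
    any, the statistic is defined as 0 with a warning.
    """
    if not 0.0 < lam <= 1.0:
        raise ValueError("lambda must be in (0, 1]")
    if len(maps) != len(pockets_per_pair):
        raise ValueError("one pocket set per map required")
    total = qualifying = 0
    for loc, ps in zip(maps, pockets_per_pair):
        positives = loc.values[loc.values > 0]
        if positives.size == 0:
            continue
        thresh = _top_lambda_threshold(positives, lam)
        for pocket in ps.pockets:
            vals = _pocket_values(loc.values, pocket)
            vals = vals[vals > 0]
            total += vals.size
            if thresh is not None:
                qualifying += int(np.sum(vals >= thresh))
    if total == 0:
        warnings.warn("no positive map values inside any pocket; relevance = 0")
        return 0.0
    return 100.0 * qualifying / total


# -- PSSM --------------------------------------------------------------


def parse_pssm(path) -> PSSMProfile:
    """Parse a PSI-BLAST ASCII PSSM (the 20-column integer score block).

    Accepts the standard stand-alone PSI-BLAST output: a title line, a
    header row with 20 (or 40) residue column labels, then one row per
    query position ``idx residue s1 .. s20 [...]``.  Errors carry the
    offending line number.
    """
    scores: list[list[float]] = []
    consensus: list[str] = []
    header_cols: list[str] | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            parts = raw.split()
            if not parts:
                continue
            if header_cols is None:
                if parts[:20] == list(PSSM_ALPHABET) or (
                    len(parts) >= 20 and all(p in PSSM_ALPHABET and len(p) == 1
                                             for p in parts[:20])
                ):
                    header_cols = parts[:20]
                    if header_cols != list(PSSM_ALPHABET):
                        raise ValueError(
                            f"{path}:{lineno}: unexpected PSSM column order"
                        )
                continue
            if not parts[0].isdigit():
                break  # footer (K/Lambda block) ends the matrix
            if len(parts) < 22:
                raise ValueError(
                    f"{path}:{lineno}: expected index, residue and 20 scores, "
                    f"got {len(parts)} fields"
                )
            idx, res = int(parts[0]), parts[1]
            if idx != len(scores) + 1:
                raise ValueError(f"{path}:{lineno}: non-consecutive position {idx}")
            if len(res) != 1:
                raise ValueError(f"{path}:{lineno}: bad residue field {res!r}")
            try:
                row = [float(x) for x in parts[2:22]]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric score ({exc})") from None
            scores.append(row)
            consensus.append(res)
    if header_cols is None or not scores:
        raise ValueError(f"{path}: no PSSM score block found")
    return PSSMProfile(scores=np.array(scores, dtype=float),
                       consensus="".join(consensus))


def write_pssm(path, profile: PSSMProfile) -> None:
    """Write a profile in the PSI-BLAST ASCII dialect read by :func:`parse_pssm`."""
    with open(path, "w") as fh:
        fh.write("Last position-specific scoring matrix computed\n")
        fh.write(" " * 10 + "  ".join(PSSM_ALPHABET) + "\n")
        for i, (res, row) in enumerate(zip(profile.consensus, profile.scores), start=1):
            cells = " ".join(f"{int(round(v)):3d}" for v in row)
            fh.write(f"{i:5d} {res} {cells}\n")


def pssm_motif_positions(profile: PSSMProfile, threshold: float,
                         pair_id: str = "", sequence: str | None = None) -> AnnotatedSites:
    """Conserved-motif positions: own-residue PSSM score >= threshold.

    The score examined at each position is the column of the sequence's own
    residue there.  ``sequence`` defaults to the profile's consensus and
    must match the profile length.
    """
    seq = profile.consensus if sequence is None else sequence
    if len(seq) != profile.length:
        raise ValueError(f"sequence length {len(seq)} != profile length {profile.length}")
    col = {a: i for i, a in enumerate(PSSM_ALPHABET)}
    positions = []
    for i, res in enumerate(seq):
        if res not in col:
            continue  # non-standard residue has no PSSM column
        if profile.scores[i, col[res]] >= threshold:
            positions.append(i + 1)
    return AnnotatedSites(pair_id=pair_id, positions=tuple(positions), kind="motif")


def filter_motifs_outside_binding_region(motifs: AnnotatedSites,
                                         binding: AnnotatedSites) -> AnnotatedSites:
    """Keep motif positions strictly outside [min(binding), max(binding)]."""
    if not binding.positions:
        raise ValueError("binding sites must be non-empty")
    lo, hi = min(binding.positions), max(binding.positions)
    kept = tuple(p for p in motifs.positions if p < lo or p > hi)
    return AnnotatedSites(pair_id=motifs.pair_id, positions=kept, kind="motif")
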