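"""Fully in-silico interaction datasets with planted, recoverable signal.

The generator emulates the statistical structure of kinase-inhibitor Kd
panels: the label distribution is heavily skewed toward the assay floor of
pKd = 5 (weak, unobserved interactions), sequences are length-bounded, and
affinity above the floor is causally driven by short sequence motifs
planted into a subset of the proteins.  Each motif occurrence contributes a
fixed amount of pKd; compounds add a per-compound potency offset and
Gaussian noise perturbs the label, clipped at 5 from below.  Pairs whose
protein carries no motif sit at pKd = 5 exactly, and the share of such
pairs is controlled exactly by ``weak_fraction``.

Because the motif positions are recorded as ground truth, a model trained
on these data can be audited: localization maps should concentrate weight
near the planted motifs, which the matching statistic quantifies against a
random-site permutation baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .encoding import CANONICAL_AMINO_ACIDS, InteractionRecord, pkd_to_kd
from .explain_eval import PSSM_ALPHABET, AnnotatedSites, PSSMProfile, write_pssm

__all__ = ["SyntheticSpec", "SyntheticDataset", "generate", "export",
           "VALID_SMILES_EXAMPLES"]

#: Characters used for synthetic SMILES-like strings (not chemically valid).
SMILES_LIKE_ALPHABET = "CNOSPc=#()123[]nos"

#: A few real, parseable SMILES for canonicalization/fingerprint tests.
VALID_SMILES_EXAMPLES = [
    ("ethanol", "CCO"),
    ("benzene", "c1ccccc1"),
    ("aspirin", "CC(=O)Oc1ccccc1C(=O)O"),
    ("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C"),
    ("ibuprofen", "CC(C)Cc1ccc(cc1)C(C)C(=O)O"),
    ("paracetamol", "CC(=O)Nc1ccc(O)cc1"),
    ("nicotine", "CN1CCCC1c1cccnc1"),
    ("glucose", "OCC1OC(O)C(O)C(O)C1O"),
    ("toluene", "Cc1ccccc1"),
    ("pyridine", "c1ccncc1"),
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator configuration; defaults describe the standard study setting."""

    n_proteins: int = 40
    n_compounds: int = 30
    n_pairs: int = 1000
    prot_len_range: tuple[int, int] = (80, 120)
    smiles_len_range: tuple[int, int] = (38, 72)
    #: (motif k-mer, pKd contribution per occurrence)
    motif_library: tuple[tuple[str, float], ...] = (("HCWKYM", 2.0),)
    weak_fraction: float = 0.7
    noise_sd: float = 0.2
    #: max planted occurrences per signal protein (uniform 1..max)
    max_occurrences: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.weak_fraction <= 1.0:
            raise ValueError("weak_fraction must be in [0,1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for motif, _ in self.motif_library:
            if len(motif) > self.prot_len_range[0]:
                raise ValueError(f"motif {motif!r} longer than min protein length")


@dataclass
class SyntheticDataset:
    records: list[InteractionRecord]
    truth_sites: dict[str, AnnotatedSites]  # pair_id -> planted motif centers
    truth_model: dict = field(default_factory=dict)
    protein_seqs: dict[str, str] = field(default_factory=dict)
    protein_sites: dict[str, tuple[int, ...]] = field(default_factory=dict)


def pair_id(protein_id: str, compound_id: str) -> str:
    return f"{protein_id}|{compound_id}"


def _plant_motifs(seq: list[str], motifs: list[tuple[str, float]], rng) -> tuple[list[int], float]:
    """Insert motifs at non-overlapping positions; return centers and pKd sum."""
    length = len(seq)
    occupied: list[tuple[int, int]] = []
    centers: list[int] = []
    contrib = 0.0
    for motif, value in motifs:
        m = len(motif)
        for _ in range(200):  # rejection-sample a free slot
            start = int(rng.integers(0, length - m + 1))
            if all(start + m <= lo or start >= hi for lo, hi in occupied):
                occupied.append((start, start + m))
                seq[start : start + m] = list(motif)
                centers.append(start + m // 2 + 1)  # 1-based center
                contrib += value
                break
    return sorted(centers), contrib


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate a reproducible synthetic interaction dataset."""
    rng = np.random.default_rng(spec.seed)
    aa = np.array(list(CANONICAL_AMINO_ACIDS))
    smi_alpha = np.array(list(SMILES_LIKE_ALPHABET))

    n_weak_prot = int(round(spec.weak_fraction * spec.n_proteins))
    protein_seqs: dict[str, str] = {}
    protein_sites: dict[str, tuple[int, ...]] = {}
    protein_contrib: dict[str, float] = {}
    weak_proteins: list[str] = []
    signal_proteins: list[str] = []
    for i in range(spec.n_proteins):
        pid = f"P{i:04d}"
        length = int(rng.integers(spec.prot_len_range[0], spec.prot_len_range[1] + 1))
        seq = list(aa[rng.integers(0, len(aa), size=length)])
        if i < n_weak_prot:
            centers: list[int] = []
            contrib = 0.0
            weak_proteins.append(pid)
        else:
            n_occ = int(rng.integers(1, spec.max_occurrences + 1))
            motifs = [spec.motif_library[int(rng.integers(0, len(spec.motif_library)))]
                      for _ in range(n_occ)]
            centers, contrib = _plant_motifs(seq, motifs, rng)
            signal_proteins.append(pid)
        protein_seqs[pid] = "".join(seq)
        protein_sites[pid] = tuple(centers)
        protein_contrib[pid] = contrib

    compound_smiles: dict[str, str] = {}
    compound_effect: dict[str, float] = {}
    for j in range(spec.n_compounds):
        cid = f"C{j:04d}"
        length = int(rng.integers(spec.smiles_len_range[0], spec.smiles_len_range[1] + 1))
        compound_smiles[cid] = "".join(smi_alpha[rng.integers(0, len(smi_alpha), size=length)])
        compound_effect[cid] = float(rng.uniform(0.0, 1.0))

    # Exact weak-pair share: sample weak and signal pairs separately.
    n_weak_pairs = int(round(spec.weak_fraction * spec.n_pairs))
    n_signal_pairs = spec.n_pairs - n_weak_pairs
    if n_signal_pairs > 0 and not signal_proteins:
        raise ValueError("weak_fraction < 1 requires at least one signal protein")
    if n_weak_pairs > 0 and not weak_proteins:
        raise ValueError("weak_fraction > 0 requires at least one weak protein")

    def sample_pairs(prots: list[str], count: int) -> list[tuple[str, str]]:
        if count == 0:
            return []
        universe = [(p, c) for p in prots for c in compound_smiles]
        if count > len(universe):
            raise ValueError("more pairs requested than distinct combinations")
        sel = rng.choice(len(universe), size=count, replace=False)
        return [universe[k] for k in sorted(sel)]

    records: list[InteractionRecord] = []
    truth_sites: dict[str, AnnotatedSites] = {}
    for pid, cid in sample_pairs(weak_proteins, n_weak_pairs) + sample_pairs(
        signal_proteins, n_signal_pairs
    ):
        if protein_contrib[pid] > 0:
            pkd = 5.0 + protein_contrib[pid] + compound_effect[cid]
            if spec.noise_sd > 0:
                pkd += float(rng.normal(0.0, spec.noise_sd))
            pkd = max(pkd, 5.0)
        else:
            pkd = 5.0
        rec = InteractionRecord(
            protein_id=pid, protein_seq=protein_seqs[pid], compound_id=cid,
            smiles=compound_smiles[cid], kd_nM=pkd_to_kd(pkd), pkd=pkd,
        )
        records.append(rec)
        if protein_sites[pid]:
            truth_sites[pair_id(pid, cid)] = AnnotatedSites(
                pair_id=pair_id(pid, cid), positions=protein_sites[pid], kind="binding"
            )
    truth_model = {
        "motif_library": list(spec.motif_library),
        "protein_contrib": protein_contrib,
        "compound_effect": compound_effect,
        "noise_sd": spec.noise_sd,
    }
    return SyntheticDataset(records=records, truth_sites=truth_sites,
                            truth_model=truth_model, protein_seqs=protein_seqs,
                            protein_sites=protein_sites)


def _toy_pssm(seq: str, sites: tuple[int, ...], motif_score: float = 9.0,
              base_score: float = 2.0, off_score: float = -1.0) -> PSSMProfile:
    """Profile whose own-residue score is high at planted-motif positions."""
    scores = np.full((len(seq), 20), off_score)
    col = {a: i for i, a in enumerate(PSSM_ALPHABET)}
    site_set = set(sites)
    for i, res in enumerate(seq):
        scores[i, col[res]] = motif_score if (i + 1) in site_set else base_score
    return PSSMProfile(scores=scores, consensus=seq)


def export(dataset: SyntheticDataset, out_dir) -> dict[str, Path]:
    """Write the dataset in the formats the pipeline reads.

    Emits ``interactions.csv``, ``proteins.fasta``, ``compounds.smi``,
    ``sites.tsv`` (truth sites as binding annotations) and one toy PSSM per
    protein under ``pssm/``.  Re-reading the files reproduces the in-memory
    dataset.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    from . import io as xio  # local import to avoid cycle

    paths["interactions"] = out / "interactions.csv"
    xio.write_interactions(paths["interactions"], dataset.records)

    paths["fasta"] = out / "proteins.fasta"
    with open(paths["fasta"], "w") as fh:
        for pid, seq in dataset.protein_seqs.items():
            fh.write(f">{pid}\n{seq}\n")

    paths["smi"] = out / "compounds.smi"
    seen = {}
    for r in dataset.records:
        seen.setdefault(r.compound_id, r.smiles)
    with open(paths["smi"], "w") as fh:
        for cid, smi in seen.items():
            fh.write(f"{smi} {cid}\n")

    paths["sites"] = out / "sites.tsv"
    xio.write_sites(paths["sites"], dataset.truth_sites.values())

    pssm_dir = out / "pssm"
    pssm_dir.mkdir(exist_ok=True)
    for pid, seq in dataset.protein_seqs.items():
        write_pssm(pssm_dir / f"{pid}.pssm", _toy_pssm(seq, dataset.protein_sites[pid]))
    paths["pssm_dir"] = pssm_dir
    return paths
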