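"""Seeded generators for motif-governed labeled peptide sets, toy
proteomes, mutation tables, and external-predictor rank tables.

These emulate the statistical structure of the real inputs — anchored
positives, proteome-like negatives, severe class imbalance, cohort
carrier counts — so every other module is testable without downloads.
All generators are fully determined by their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from appm.codec import ALPHABET
from appm.neoantigen import DriverMutation

_AA = np.array(list(ALPHABET))
_AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

#: uniform background over the 20 residues (clean analytic expectations)
BACKGROUND_UNIFORM: Dict[str, float] = {aa: 1.0 / 20 for aa in ALPHABET}

#: rough human-proteome residue frequencies (SwissProt-like), normalized
BACKGROUND_PROTEOME: Dict[str, float] = {
    "A": 0.0826, "C": 0.0137, "D": 0.0546, "E": 0.0672, "F": 0.0386,
    "G": 0.0708, "H": 0.0227, "I": 0.0593, "K": 0.0581, "L": 0.0965,
    "M": 0.0241, "N": 0.0406, "P": 0.0472, "Q": 0.0393, "R": 0.0553,
    "S": 0.0660, "T": 0.0535, "V": 0.0686, "W": 0.0110, "Y": 0.0292,
}


def _normalize(dist: Mapping[str, float]) -> np.ndarray:
    probs = np.array([dist.get(aa, 0.0) for aa in ALPHABET], dtype=np.float64)
    total = probs.sum()
    if total <= 0:
        raise ValueError("background distribution has no mass")
    return probs / total


@dataclass(frozen=True)
class SyntheticAlleleSpec:
    """Generator spec for one synthetic allele.

    ``anchor_rules`` maps a 1-based position (negative indexes from the
    end: -1 = last position of each peptide) to ``(residues, adherence)``;
    with probability ``adherence`` an anchored position draws uniformly from
    ``residues``, otherwise from the background.
    """

    name: str = "A*02:01"
    length_weights: Mapping[int, float] = field(
        default_factory=lambda: {8: 0.15, 9: 0.55, 10: 0.2, 11: 0.1}
    )
    anchor_rules: Mapping[int, Tuple[str, float]] = field(
        default_factory=lambda: {2: ("L", 0.9), -1: ("VL", 0.9)}
    )
    background: Mapping[str, float] = field(default_factory=lambda: BACKGROUND_UNIFORM)
    imbalance_ratio: int = 39
    n_positives: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.imbalance_ratio < 1:
            raise ValueError("imbalance_ratio must be >= 1")
        if self.n_positives < 1:
            raise ValueError("n_positives must be >= 1")
        w = dict(self.length_weights)
        if not w or any(length not in (8, 9, 10, 11) for length in w):
            raise ValueError("length_weights keys must be in {8, 9, 10, 11}")
        if abs(sum(w.values()) - 1.0) > 1e-9:
            raise ValueError("length_weights must sum to 1")
        for pos, (residues, adherence) in dict(self.anchor_rules).items():
            if not residues or any(aa not in ALPHABET for aa in residues):
                raise ValueError(f"bad anchor residue set {residues!r} at {pos}")
            if not 0.0 <= adherence <= 1.0:
                raise ValueError(f"adherence {adherence} outside [0, 1]")
            if pos == 0:
                raise ValueError("anchor positions are 1-based (or negative)")

    def resolved_anchors(self, length: int) -> Dict[int, Tuple[str, float]]:
        """Anchor rules with negative positions resolved for one length
        (0-based position keys)."""
        out: Dict[int, Tuple[str, float]] = {}
        for pos, rule in self.anchor_rules.items():
            idx = pos - 1 if pos > 0 else length + pos
            if 0 <= idx < length:
                out[idx] = rule
        return out

    def generating_pfm(self, length: int) -> np.ndarray:
        """The exact position frequency matrix positives are drawn from."""
        bg = _normalize(self.background)
        pfm = np.tile(bg, (length, 1))
        for idx, (residues, adherence) in self.resolved_anchors(length).items():
            anchor = np.zeros(len(ALPHABET))
            for aa in residues:
                anchor[_AA_INDEX[aa]] = 1.0 / len(residues)
            pfm[idx] = adherence * anchor + (1 - adherence) * bg
        return pfm


def _draw_lengths(spec: SyntheticAlleleSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    lengths = np.array(sorted(spec.length_weights))
    weights = np.array([spec.length_weights[int(l)] for l in lengths])
    return rng.choice(lengths, size=n, p=weights / weights.sum())


def _draw_background(n_rows: int, length: int, bg: np.ndarray, rng) -> List[str]:
    mat = rng.choice(20, size=(n_rows, length), p=bg)
    return ["".join(_AA[row]) for row in mat]


def generate_dataset(
    spec: SyntheticAlleleSpec,
) -> Tuple[pd.DataFrame, Dict[int, np.ndarray]]:
    """Labeled peptide table plus the ground-truth generating PFMs.

    Positives are drawn with anchors enforced at the stated probabilities;
    exactly ``imbalance_ratio × n_positives`` negatives are drawn from the
    background. Returns ``(table, {length: pfm})``.
    """
    rng = np.random.default_rng(spec.seed)
    bg = _normalize(spec.background)

    pos_seqs: List[str] = []
    for length in _draw_lengths(spec, spec.n_positives, rng):
        length = int(length)
        pfm = spec.generating_pfm(length)
        residues = [str(rng.choice(_AA, p=pfm[i])) for i in range(length)]
        pos_seqs.append("".join(residues))

    n_neg = spec.imbalance_ratio * spec.n_positives
    neg_seqs: List[str] = []
    for length in _draw_lengths(spec, n_neg, rng):
        neg_seqs.append(_draw_background(1, int(length), bg, rng)[0])

    table = pd.DataFrame(
        {
            "peptide": pos_seqs + neg_seqs,
            "allele": spec.name,
            "label": [1] * len(pos_seqs) + [0] * len(neg_seqs),
        }
    )
    pfms = {length: spec.generating_pfm(length) for length in sorted(spec.length_weights)}
    return table, pfms


def generate_proteome(
    n_proteins: int,
    length_range: Tuple[int, int] = (150, 300),
    seed: int = 0,
    hits_per_protein: int = 0,
    hit_length: int = 9,
    background: Mapping[str, float] = BACKGROUND_UNIFORM,
) -> Tuple[Dict[str, str], List[Tuple[str, str, int]]]:
    """Random toy proteome with designated hit substrings.

    Returns ``(proteome, hits)`` where each hit is
    ``(sequence, protein_id, 0-based offset)`` and
    ``proteome[pid][off:off+len] == sequence`` holds for every hit.
    """
    lo, hi = length_range
    if lo < 11:
        raise ValueError("protein lengths must be >= 11")
    rng = np.random.default_rng(seed)
    bg = _normalize(background)
    proteome: Dict[str, str] = {}
    hits: List[Tuple[str, str, int]] = []
    for i in range(n_proteins):
        pid = f"SYN{i:04d}"
        length = int(rng.integers(lo, hi + 1))
        seq = _draw_background(1, length, bg, rng)[0]
        proteome[pid] = seq
        if hits_per_protein:
            starts = rng.choice(
                length - hit_length + 1,
                size=min(hits_per_protein, length - hit_length + 1),
                replace=False,
            )
            for off in sorted(int(s) for s in starts):
                hits.append((seq[off:off + hit_length], pid, off))
    return proteome, hits


def generate_mutation_table(
    proteome: Mapping[str, str],
    n_mutations: int,
    seed: int = 0,
    cohort_size: int = 1000,
) -> List[DriverMutation]:
    """Random missense mutations with valid wild-type residues.

    Positions deliberately include near-terminus cases (< 8 residues from a
    protein end) so context-clipping logic gets exercised; carrier counts
    are drawn within the cohort size.
    """
    if not proteome:
        raise ValueError("proteome is empty")
    rng = np.random.default_rng(seed)
    pids = sorted(proteome)
    muts: List[DriverMutation] = []
    for i in range(n_mutations):
        pid = pids[int(rng.integers(len(pids)))]
        protein = proteome[pid]
        n = len(protein)
        # cycle interior / N-terminal / C-terminal placements for coverage
        kind = i % 3
        if kind == 1:
            pos = int(rng.integers(1, min(8, n) + 1))
        elif kind == 2:
            pos = int(rng.integers(max(1, n - 7), n + 1))
        else:
            pos = int(rng.integers(1, n + 1))
        wt = protein[pos - 1]
        mut = str(rng.choice([aa for aa in ALPHABET if aa != wt]))
        carriers = int(rng.integers(1, max(2, cohort_size // 10)))
        muts.append(
            DriverMutation(
                gene=f"GENE{i:03d}",
                protein_id=pid,
                position=pos,
                wt_aa=wt,
                mut_aa=mut,
                carriers=carriers,
                cohort_size=cohort_size,
                cancer_type="SYN",
            )
        )
    return muts


def generate_rank_table(
    peptides: Sequence[str],
    binders: Set[str],
    seed: int = 0,
    binder_rank_max: float = 2.0,
) -> Dict[str, float]:
    """External-predictor-style percentile ranks: designated binders get
    ranks in (0, binder_rank_max], everything else in (binder_rank_max, 100]."""
    rng = np.random.default_rng(seed)
    out: Dict[str, float] = {}
    for pep in peptides:
        if pep in binders:
            out[pep] = float(rng.uniform(1e-6, binder_rank_max))
        else:
            out[pep] = float(rng.uniform(binder_rank_max + 1e-6, 100.0))
    return out
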