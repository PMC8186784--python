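"""Presentation-motif analysis: position frequency matrices, anchor
positions by information content, amino-acid property-class summaries,
and motif similarity."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np

from appm.codec import ALPHABET

_AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

# The property scheme is a declared convention (overrideable), applied to
# anchor-residue summaries.
DEFAULT_PROPERTY_CLASSES: Dict[str, str] = {
    "D": "acidic", "E": "acidic",
    "K": "basic", "R": "basic", "H": "basic",
    "A": "hydrophobic", "V": "hydrophobic", "L": "hydrophobic",
    "I": "hydrophobic", "M": "hydrophobic", "F": "hydrophobic",
    "W": "hydrophobic", "C": "hydrophobic",
    "S": "polar", "T": "polar", "N": "polar", "Q": "polar", "Y": "polar",
    "G": "neutral", "P": "neutral",
}


@dataclass
class PositionFrequencyMatrix:
    """Per-position amino-acid frequencies over same-length peptides.

    ``freq`` has one row per peptide position and 20 columns in alphabet
    order; every row sums to 1.
    """

    length: int
    freq: np.ndarray = field(repr=False)
    support: int = 1
    allele: Optional[str] = None

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=np.float64)
        if self.freq.shape != (self.length, len(ALPHABET)):
            raise ValueError(
                f"freq shape {self.freq.shape} != ({self.length}, {len(ALPHABET)})"
            )
        if not np.allclose(self.freq.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("every pfm row must sum to 1")
        if self.support < 1:
            raise ValueError("support must be >= 1")


def build_pfm(
    peptides: Sequence[str],
    pseudocount: float = 0.0,
    allele: Optional[str] = None,
) -> PositionFrequencyMatrix:
    """Count-based PFM from a nonempty set of same-length peptides."""
    if not peptides:
        raise ValueError("need at least one peptide")
    seqs = [p.sequence if hasattr(p, "sequence") else str(p).upper() for p in peptides]
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("all peptides must have the same length")
    counts = np.full((length, len(ALPHABET)), pseudocount, dtype=np.float64)
    for s in seqs:
        for i, aa in enumerate(s):
            counts[i, _AA_INDEX[aa]] += 1
    freq = counts / counts.sum(axis=1, keepdims=True)
    return PositionFrequencyMatrix(
        length=length, freq=freq, support=len(seqs), allele=allele
    )


def information_content(pfm: PositionFrequencyMatrix) -> np.ndarray:
    """Shannon information content per position against a uniform background:
    IC(i) = log2(20) + Σ_a f·log2(f), with 0·log(0) := 0. Range [0, log2 20]."""
    f = pfm.freq
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(f > 0, f * np.log2(f), 0.0)
    return np.log2(len(ALPHABET)) + plogp.sum(axis=1)


def find_anchors(pfm: PositionFrequencyMatrix, k: int = 2) -> Tuple[int, ...]:
    """The k positions (1-based) of highest information content, ties broken
    toward the smaller position index; returned in ascending position order."""
    if k > pfm.length:
        raise ValueError(f"k={k} exceeds peptide length {pfm.length}")
    ic = information_content(pfm)
    order = sorted(range(pfm.length), key=lambda i: (-ic[i], i))
    return tuple(sorted(i + 1 for i in order[:k]))


def property_profile(
    pfm: PositionFrequencyMatrix,
    positions: Sequence[int],
    classes: Mapping[str, str] = DEFAULT_PROPERTY_CLASSES,
) -> Dict[str, float]:
    """Frequency mass per property class at the given 1-based positions,
    averaged over positions. Fractions sum to 1."""
    if not positions:
        raise ValueError("need at least one position")
    for pos in positions:
        if not 1 <= pos <= pfm.length:
            raise ValueError(f"position {pos} outside [1, {pfm.length}]")
    if set(classes) != set(ALPHABET):
        raise ValueError("property-class map must cover all 20 amino acids exactly")
    out: Dict[str, float] = {c: 0.0 for c in sorted(set(classes.values()))}
    for pos in positions:
        row = pfm.freq[pos - 1]
        for aa, cls in classes.items():
            out[cls] += row[_AA_INDEX[aa]]
    for cls in out:
        out[cls] /= len(positions)
    return out


def motif_similarity(
    pfm_a: PositionFrequencyMatrix, pfm_b: PositionFrequencyMatrix
) -> float:
    """Mean per-position cosine similarity between frequency rows; symmetric,
    1.0 on identical motifs, in [0, 1] for nonnegative frequencies."""
    if pfm_a.length != pfm_b.length:
        raise ValueError(
            f"length mismatch: {pfm_a.length} vs {pfm_b.length}"
        )
    sims = []
    for ra, rb in zip(pfm_a.freq, pfm_b.freq):
        denom = np.linalg.norm(ra) * np.linalg.norm(rb)
        sims.append(float(ra @ rb / denom) if denom > 0 else 0.0)
    return float(np.mean(sims))


def pfm_to_frame(pfm: PositionFrequencyMatrix):
    """PFM as a pandas DataFrame (positions × residues) for CSV output."""
    import pandas as pd

    return pd.DataFrame(
        pfm.freq,
        index=[f"P{i}" for i in range(1, pfm.length + 1)],
        columns=list(ALPHABET),
    )


def plot_logo(pfm: PositionFrequencyMatrix, ax=None):
    """Minimal information-content logo: stacked letter heights per position,
    scaled by IC. Requires matplotlib; returns the axes."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(0.8 * pfm.length, 3))
    ic = information_content(pfm)
    for pos in range(pfm.length):
        heights = pfm.freq[pos] * ic[pos]
        bottom = 0.0
        for idx in np.argsort(heights):
            h = heights[idx]
            if h <= 1e-3:
                continue
            ax.text(
                pos + 1, bottom + h / 2, ALPHABET[idx],
                ha="center", va="center", fontsize=8 + 10 * h / np.log2(20),
            )
            bottom += h
    ax.set_xlim(0.5, pfm.length + 0.5)
    ax.set_ylim(0, np.log2(20))
    ax.set_xlabel("position")
    ax.set_ylabel("bits")
    return ax
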