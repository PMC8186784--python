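"""Hit/decoy benchmark construction, the three performance metrics,
rank thresholding, and the two-predictor intersection ensemble.

For each MS-identified hit, 99 decoy peptides (by default) are sampled
from the hit's source protein across the four lengths 8–11 with a
balanced per-length allocation; 99 is not divisible by 4, so the deficit
goes to length 11 (the rarest class in elution data): 25/25/25/24.
Decoys that appear in the model's training data, or that duplicate a
sequence already sampled from another protein, are then removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

logger = logging.getLogger(__name__)

DECOY_LENGTHS = (8, 9, 10, 11)


class ProteinLookupError(KeyError):
    pass


@dataclass(frozen=True)
class BenchmarkRecord:
    peptide: str
    label: int
    source_protein: str
    offset: int  # 0-based offset within the source protein; -1 if unknown
    length: int


@dataclass
class BenchmarkSet:
    """Hits plus length-stratified decoys with provenance, after filtering.

    ``prefilter_decoy_counts`` maps each hit sequence to the number of decoys
    sampled for it before the training-overlap and duplicate filters ran.
    """

    allele: Optional[str]
    records: List[BenchmarkRecord]
    decoys_per_hit: int = 99
    prefilter_decoy_counts: Dict[str, int] = field(default_factory=dict)

    @property
    def hits(self) -> List[BenchmarkRecord]:
        return [r for r in self.records if r.label == 1]

    @property
    def decoys(self) -> List[BenchmarkRecord]:
        return [r for r in self.records if r.label == 0]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class Metrics:
    """The three benchmark metrics; ``None`` marks an undefined ratio
    (division by zero is never silently reported as 0)."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]


def length_allocation(decoys_per_hit: int, lengths: Sequence[int] = DECOY_LENGTHS) -> Dict[int, int]:
    """Balanced per-length decoy allocation; any remainder is given to the
    shorter lengths so the deficit lands on length 11 (e.g. 99 → 25/25/25/24)."""
    if decoys_per_hit < len(lengths):
        raise ValueError(f"decoys_per_hit must be >= {len(lengths)}")
    base, extra = divmod(decoys_per_hit, len(lengths))
    return {
        length: base + (1 if i < extra else 0)
        for i, length in enumerate(sorted(lengths))
    }


def generate_decoys(
    hits: Sequence[Tuple[str, str]],
    proteome: Mapping[str, str],
    training_peptides: Set[str],
    decoys_per_hit: int = 99,
    seed: int = 0,
    allele: Optional[str] = None,
) -> BenchmarkSet:
    """Build a hit/decoy benchmark from (hit sequence, source protein id) pairs.

    Per hit, decoys are drawn uniformly without replacement from all
    substrings of the hit's source protein of lengths 8–11 that are not MS
    hits, with the balanced per-length allocation. Training-set members and
    cross-protein duplicate sequences are then removed (first occurrence in
    seeded sampling order wins). Hits themselves are deduplicated by
    sequence; provenance (source protein, offset) is retained throughout.
    """
    rng = np.random.default_rng(seed)
    hit_seqs = {seq for seq, _ in hits}
    alloc = length_allocation(decoys_per_hit)

    records: List[BenchmarkRecord] = []
    seen: Set[str] = set()
    prefilter_counts: Dict[str, int] = {}

    for hit_seq, protein_id in hits:
        if protein_id not in proteome:
            raise ProteinLookupError(f"protein {protein_id!r} absent from FASTA")
        protein = proteome[protein_id]
        if hit_seq not in seen:
            offset = protein.find(hit_seq)
            records.append(
                BenchmarkRecord(hit_seq, 1, protein_id, offset, len(hit_seq))
            )
            seen.add(hit_seq)

        sampled: List[Tuple[str, int, int]] = []  # (sequence, offset, length)
        for length, want in alloc.items():
            if length > len(protein):
                logger.warning(
                    "protein %s (%d aa) shorter than decoy length %d; skipping",
                    protein_id, len(protein), length,
                )
                continue
            candidates = [
                (protein[i:i + length], i)
                for i in range(len(protein) - length + 1)
                if protein[i:i + length] not in hit_seqs
            ]
            if len(candidates) < want:
                logger.warning(
                    "protein %s has only %d eligible %d-mers (wanted %d); taking all",
                    protein_id, len(candidates), length, want,
                )
                chosen = candidates
            else:
                idx = rng.choice(len(candidates), size=want, replace=False)
                chosen = [candidates[i] for i in idx]
            sampled.extend((seq, off, length) for seq, off in chosen)

        prefilter_counts[hit_seq] = prefilter_counts.get(hit_seq, 0) + len(sampled)
        for seq, off, length in sampled:
            if seq in training_peptides or seq in seen:
                continue
            records.append(BenchmarkRecord(seq, 0, protein_id, off, length))
            seen.add(seq)

    return BenchmarkSet(
        allele=allele,
        records=records,
        decoys_per_hit=decoys_per_hit,
        prefilter_decoy_counts=prefilter_counts,
    )


def compute_metrics(counts: ConfusionCounts) -> Metrics:
    """sensitivity = tp/(tp+fn); specificity = tn/(tn+fp); ppv = tp/(tp+fp).

    Each ratio is ``None`` when its denominator is zero.
    """
    def _ratio(num: int, den: int) -> Optional[float]:
        return num / den if den > 0 else None

    return Metrics(
        sensitivity=_ratio(counts.tp, counts.tp + counts.fn),
        specificity=_ratio(counts.tn, counts.tn + counts.fp),
        ppv=_ratio(counts.tp, counts.tp + counts.fp),
    )


def confusion_from_calls(
    records: Iterable[BenchmarkRecord], positive_calls: Set[str]
) -> ConfusionCounts:
    """Tally a benchmark against a set of peptides called positive."""
    tp = fp = tn = fn = 0
    for r in records:
        called = r.peptide in positive_calls
        if r.label == 1:
            tp += called
            fn += not called
        else:
            fp += called
            tn += not called
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def call_binders_by_rank(
    rank_table: Mapping[str, float], threshold_percent: float = 2.0
) -> Set[str]:
    """Peptides whose percentile rank is ≤ the threshold (top 2% by default
    — the conventional binder cutoff)."""
    for pep, rank in rank_table.items():
        if not 0.0 < rank <= 100.0:
            raise ValueError(f"rank {rank} for {pep!r} outside (0, 100]")
    return {pep for pep, rank in rank_table.items() if rank <= threshold_percent}


def combine_predictions(calls_a: Set[str], calls_b: Set[str]) -> Set[str]:
    """Intersection ensemble: only peptides called positive by both
    predictors are regarded as positives."""
    return set(calls_a) & set(calls_b)


def false_positive_overlap(
    fp_a: Set[str], fp_b: Set[str], method: str = "jaccard"
) -> Optional[float]:
    """Overlap fraction between two false-positive sets.

    ``jaccard`` (default): |A∩B| / |A∪B|. ``min``: |A∩B| / min(|A|, |B|).
    Returns ``None`` when both sets are empty.
    """
    a, b = set(fp_a), set(fp_b)
    if not a and not b:
        return None
    inter = len(a & b)
    if method == "jaccard":
        return inter / len(a | b)
    if method == "min":
        smaller = min(len(a), len(b))
        return inter / smaller if smaller else None
    raise ValueError(f"unknown overlap method {method!r}")
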