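"""Neoantigen candidate extraction from driver missense mutations.

For each mutation a context is cut from the protein: the mutant residue
centered with L−1 wild-type flanks per side for window length L (a 17-mer
for 9-mers), clipped at protein termini. A window of size L then slides
across the context from "mutation at the last position" to "mutation at
the first position". A full context yields exactly L windows per length —
9 nine-mers, and 8+9+10+11 = 38 candidates over all four lengths.

Coordinates are 1-based throughout (standard for p.-notation); window
``mutation_offset`` is 1-based within the peptide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from appm.codec import ALPHABET
from appm.benchmark import combine_predictions

logger = logging.getLogger(__name__)

CANDIDATE_LENGTHS = (8, 9, 10, 11)
DEFAULT_FLANK = 8


class ReferenceMismatchError(ValueError):
    """The FASTA residue at the mutation position does not match wt_aa."""


@dataclass(frozen=True)
class DriverMutation:
    gene: str
    protein_id: str
    position: int  # 1-based protein coordinate
    wt_aa: str
    mut_aa: str
    carriers: Optional[int] = None
    cohort_size: Optional[int] = None
    cancer_type: Optional[str] = None

    def __post_init__(self) -> None:
        if self.wt_aa == self.mut_aa:
            raise ValueError(f"wt_aa == mut_aa ({self.wt_aa}) for {self.label}")
        for aa in (self.wt_aa, self.mut_aa):
            if aa not in ALPHABET:
                raise ValueError(f"invalid amino acid {aa!r} in {self.label}")
        if self.position < 1:
            raise ValueError("position must be >= 1 (1-based)")
        if (
            self.carriers is not None
            and self.cohort_size is not None
            and self.carriers > self.cohort_size
        ):
            raise ValueError("carriers cannot exceed cohort_size")

    @property
    def label(self) -> str:
        return f"{self.gene}_p.{self.wt_aa}{self.position}{self.mut_aa}"


@dataclass(frozen=True)
class CandidatePeptide:
    """A mutation-spanning window of length 8–11."""

    sequence: str
    length: int
    mutation_offset: int  # 1-based position of mut_aa within the peptide
    mutation: Optional[DriverMutation] = None

    def __post_init__(self) -> None:
        if len(self.sequence) != self.length:
            raise ValueError("length field disagrees with sequence")
        if not 1 <= self.mutation_offset <= self.length:
            raise ValueError("mutation_offset outside peptide")
        if (
            self.mutation is not None
            and self.sequence[self.mutation_offset - 1] != self.mutation.mut_aa
        ):
            raise ValueError(
                f"residue at offset {self.mutation_offset} is not the mutant "
                f"amino acid {self.mutation.mut_aa}"
            )


def extract_context(
    mutation: DriverMutation,
    proteome: Mapping[str, str],
    flank: int = DEFAULT_FLANK,
) -> Tuple[str, int]:
    """Mutant context substring around the mutation site.

    Returns ``(context, mutation_index)`` where ``mutation_index`` is the
    1-based position of the mutant residue within the context. With full
    flanks the context is 2·flank+1 = 17 residues; near a protein terminus
    it is clipped (no padding — that would fabricate sequence).
    """
    if mutation.protein_id not in proteome:
        raise KeyError(f"protein {mutation.protein_id!r} absent from FASTA")
    protein = proteome[mutation.protein_id]
    pos = mutation.position
    if pos > len(protein):
        raise ReferenceMismatchError(
            f"{mutation.label}: position {pos} beyond protein length {len(protein)}"
        )
    if protein[pos - 1] != mutation.wt_aa:
        raise ReferenceMismatchError(
            f"{mutation.label}: expected {mutation.wt_aa} at position {pos}, "
            f"found {protein[pos - 1]}"
        )
    start = max(0, pos - 1 - flank)
    end = min(len(protein), pos + flank)
    context = protein[start:pos - 1] + mutation.mut_aa + protein[pos:end]
    return context, pos - start


def sliding_windows(
    context: str,
    mutation_index: int,
    lengths: Sequence[int] = CANDIDATE_LENGTHS,
    mutation: Optional[DriverMutation] = None,
) -> List[CandidatePeptide]:
    """All length-L substrings of the context containing the mutation.

    Windows are enumerated from mutation-at-last-position to
    mutation-at-first-position. With full flanks this yields exactly L
    windows per length. Duplicate sequences within a length (repetitive
    context) are retained with distinct offsets.
    """
    if not 1 <= mutation_index <= len(context):
        raise ValueError(
            f"mutation_index {mutation_index} outside context of length {len(context)}"
        )
    out: List[CandidatePeptide] = []
    for length in lengths:
        # 1-based window start range such that the window both fits in the
        # context and contains the mutation position
        first_start = max(1, mutation_index - length + 1)
        last_start = min(mutation_index, len(context) - length + 1)
        for start in range(first_start, last_start + 1):
            seq = context[start - 1:start - 1 + length]
            out.append(
                CandidatePeptide(
                    sequence=seq,
                    length=length,
                    mutation_offset=mutation_index - start + 1,
                    mutation=mutation,
                )
            )
    return out


def candidates_for_mutation(
    mutation: DriverMutation,
    proteome: Mapping[str, str],
    lengths: Sequence[int] = CANDIDATE_LENGTHS,
    flank: Optional[int] = None,
) -> List[CandidatePeptide]:
    """All candidate peptides for one mutation across the given lengths.

    Each length L is treated the same way as the 9-mer case: a context with
    L−1 wild-type flanks per side (a (2L−1)-mer when not clipped), slid L
    times — so an interior mutation yields exactly 8+9+10+11 = 38 candidates.
    Pass an explicit ``flank`` to share one context size across lengths.
    """
    out: List[CandidatePeptide] = []
    for length in lengths:
        context, idx = extract_context(
            mutation, proteome, flank=(length - 1 if flank is None else flank)
        )
        out.extend(
            sliding_windows(context, idx, lengths=(length,), mutation=mutation)
        )
    return out


def score_candidates(
    candidates: Sequence[CandidatePeptide],
    alleles: Sequence[str],
    predictor_a,
    predictor_b_calls: Optional[Mapping[str, Set[str]]] = None,
) -> pd.DataFrame:
    """Score candidates across an allele panel and combine calls.

    ``predictor_a`` is a callable ``(allele, sequences) -> set of positive
    sequences`` (e.g. a wrapper over per-allele trained models).
    ``predictor_b_calls`` optionally maps allele → externally called binder
    sequences; when given, the combined call is the intersection rule. A
    mutation yields a putative neoantigen iff at least one combined-positive
    candidate exists over the panel.

    Alleles whose predictor raises are reported (``error`` column) and the
    rest proceed.
    """
    seqs = [c.sequence for c in candidates]
    rows = []
    for allele in alleles:
        try:
            calls_a = set(predictor_a(allele, seqs))
        except Exception as exc:  # per-allele failure must not kill the panel
            logger.error("predictor failed for %s: %s", allele, exc)
            for c in candidates:
                rows.append(
                    dict(
                        allele=allele, peptide=c.sequence, length=c.length,
                        mutation=(c.mutation.label if c.mutation else None),
                        appm_call=None, external_call=None, combined_call=None,
                        error=str(exc),
                    )
                )
            continue
        if predictor_b_calls is not None:
            calls_b = set(predictor_b_calls.get(allele, set()))
            combined = combine_predictions(calls_a, calls_b)
        else:
            calls_b = None
            combined = calls_a
        for c in candidates:
            rows.append(
                dict(
                    allele=allele, peptide=c.sequence, length=c.length,
                    mutation=(c.mutation.label if c.mutation else None),
                    appm_call=int(c.sequence in calls_a),
                    external_call=(
                        int(c.sequence in calls_b) if calls_b is not None else None
                    ),
                    combined_call=int(c.sequence in combined),
                    error=None,
                )
            )
    return pd.DataFrame(rows)


def cohort_frequency(mutation: DriverMutation) -> Optional[float]:
    """100 × carriers / cohort_size, rounded to two decimals; ``None`` when
    either count is missing."""
    if mutation.carriers is None or mutation.cohort_size is None:
        return None
    return round(100.0 * mutation.carriers / mutation.cohort_size, 2)


def shared_neoantigen_display(allele: str, peptide: str) -> str:
    """Canonical "HLA-A*03:01_VVGAGDVGK"-style display string."""
    prefix = "" if allele.startswith("HLA-") else "HLA-"
    return f"{prefix}{allele}_{peptide}"
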