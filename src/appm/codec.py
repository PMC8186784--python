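"""Fixed-shape one-hot codec for 8–11mer peptides.

Every peptide is encoded as an 11-row by 21-column binary matrix. Columns
1–20 follow the amino-acid alphabet ``ACDEFGHIKLMNPQRSTVWY`` in that order;
column 21 is the pad symbol ``Z``. Sequences shorter than 11 residues are
suffix-padded with ``Z`` rows, which keeps the P2 anchor at a fixed row
across lengths. The mapping is fixed, so encodings are bit-identical
across runs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
PAD_CHAR = "Z"
FULL_ALPHABET = ALPHABET + PAD_CHAR

MIN_LENGTH = 8
MAX_LENGTH = 11
N_COLUMNS = len(FULL_ALPHABET)  # 21

#: column index of each symbol (pad included)
COLUMN_INDEX = {aa: i for i, aa in enumerate(FULL_ALPHABET)}
_PAD_COL = COLUMN_INDEX[PAD_CHAR]

#: "A*01:01"-style allele names, optionally prefixed with "HLA-"
_ALLELE_RE = re.compile(r"^(HLA-)?[A-Z]+[0-9]*\*\d{2,}:\d{2,}[A-Z]?$")


class PeptideError(ValueError):
    """Base class for codec validation failures."""


class PeptideLengthError(PeptideError):
    """Sequence length outside the supported 8–11 range."""


class AlphabetError(PeptideError):
    """Sequence contains a character outside the 20-letter alphabet."""


class AlleleNameError(PeptideError):
    """Allele name does not match gene*group:protein nomenclature."""


class MalformedMatrixError(PeptideError):
    """Matrix violates the one-hot encoding invariants."""


def validate_sequence(sequence: str) -> str:
    """Upper-case and validate a peptide sequence, returning the canonical form."""
    seq = sequence.upper()
    if not MIN_LENGTH <= len(seq) <= MAX_LENGTH:
        raise PeptideLengthError(
            f"peptide length {len(seq)} outside [{MIN_LENGTH}, {MAX_LENGTH}]: {sequence!r}"
        )
    bad = set(seq) - set(ALPHABET)
    if bad:
        raise AlphabetError(
            f"invalid residue(s) {sorted(bad)} in {sequence!r}; "
            f"alphabet is {ALPHABET!r}"
        )
    return seq


def validate_allele(allele: str) -> str:
    if not _ALLELE_RE.match(allele):
        raise AlleleNameError(
            f"allele {allele!r} does not match gene*group:protein nomenclature "
            "(e.g. 'A*02:01')"
        )
    return allele


@dataclass(frozen=True)
class Peptide:
    """An 8–11aa sequence with optional allele and binary presentation label.

    ``label`` is 1 for an MS-identified hit, 0 for a proteome decoy, or
    ``None`` when unlabeled. Input sequences are upper-cased before
    validation (FASTA sources vary in case).
    """

    sequence: str
    allele: Optional[str] = None
    label: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", validate_sequence(self.sequence))
        if self.allele is not None:
            validate_allele(self.allele)
        if self.label is not None and self.label not in (0, 1):
            raise PeptideError(f"label must be 0, 1 or None, got {self.label!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class EncodedPeptide:
    """The fixed 11×21 one-hot matrix consumed by the classifier."""

    matrix: np.ndarray = field(repr=False)
    source_length: int

    def __post_init__(self) -> None:
        if self.matrix.shape != (MAX_LENGTH, N_COLUMNS):
            raise MalformedMatrixError(
                f"expected shape ({MAX_LENGTH}, {N_COLUMNS}), got {self.matrix.shape}"
            )


def encode_peptide(p: "Peptide | str") -> EncodedPeptide:
    """One-hot encode a peptide into the fixed 11×21 matrix.

    The first ``L`` rows one-hot the residues in order; the remaining
    ``11 − L`` rows one-hot the pad symbol ``Z``.
    """
    seq = p.sequence if isinstance(p, Peptide) else validate_sequence(p)
    matrix = np.zeros((MAX_LENGTH, N_COLUMNS), dtype=np.uint8)
    for i, aa in enumerate(seq):
        matrix[i, COLUMN_INDEX[aa]] = 1
    matrix[len(seq):, _PAD_COL] = 1
    return EncodedPeptide(matrix=matrix, source_length=len(seq))


def decode_peptide(m: EncodedPeptide) -> str:
    """Invert :func:`encode_peptide`; ``decode(encode(p)) == p`` for valid ``p``."""
    matrix = np.asarray(m.matrix)
    if matrix.shape != (MAX_LENGTH, N_COLUMNS):
        raise MalformedMatrixError(f"bad shape {matrix.shape}")
    row_sums = matrix.sum(axis=1)
    if not np.all(row_sums == 1):
        bad_rows = np.nonzero(row_sums != 1)[0].tolist()
        raise MalformedMatrixError(f"rows {bad_rows} do not sum to 1")
    cols = matrix.argmax(axis=1)
    residues = []
    seen_pad = False
    for i, c in enumerate(cols):
        if c == _PAD_COL:
            seen_pad = True
        elif seen_pad:
            raise MalformedMatrixError(f"non-pad row {i} follows a pad row")
        else:
            residues.append(FULL_ALPHABET[c])
    seq = "".join(residues)
    if not MIN_LENGTH <= len(seq) <= MAX_LENGTH:
        raise MalformedMatrixError(
            f"decoded length {len(seq)} outside [{MIN_LENGTH}, {MAX_LENGTH}]"
        )
    return seq


def encode_batch(peptides) -> np.ndarray:
    """Encode a sequence of peptides/strings into an (N, 11, 21) float array."""
    return np.stack(
        [encode_peptide(p).matrix for p in peptides]
    ).astype(np.float64)
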