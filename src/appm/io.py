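"""Readers/writers and run-manifest provenance.

Interchange dialects: CSV peptide tables (``peptide[,allele][,label]``),
FASTA proteomes, CSV external rank tables
(``peptide,allele,score,percentile_rank``), YAML configs, and JSON run
manifests recording inputs, seeds, a config hash and versions.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO

from appm.codec import PeptideError, validate_sequence

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    pass


@dataclass
class RowIssue:
    line: int
    message: str


@dataclass
class PeptideTable:
    """A validated peptide table plus the issues found while reading it."""

    frame: pd.DataFrame
    issues: List[RowIssue] = field(default_factory=list)


def read_peptide_table(path, strict: bool = False) -> PeptideTable:
    """Read and validate a ``peptide[,allele][,label]`` CSV.

    Malformed rows are reported with their 1-based file line numbers;
    ``strict=True`` aborts on the first issue, otherwise bad rows are
    skipped.
    """
    frame = pd.read_csv(path, dtype={"peptide": str})
    if "peptide" not in frame.columns:
        raise FormatError(f"{path}: missing required 'peptide' column")
    keep = []
    issues: List[RowIssue] = []
    for row_idx, raw in frame["peptide"].items():
        line_no = int(row_idx) + 2  # header is line 1
        try:
            validate_sequence(str(raw))
            keep.append(row_idx)
        except PeptideError as exc:
            issue = RowIssue(line=line_no, message=str(exc))
            if strict:
                raise FormatError(f"{path}:{line_no}: {exc}") from exc
            issues.append(issue)
            logger.warning("%s:%d skipped: %s", path, line_no, exc)
    out = frame.loc[keep].copy()
    out["peptide"] = out["peptide"].str.upper()
    if "label" in out.columns:
        out["label"] = out["label"].astype(int)
    return PeptideTable(frame=out.reset_index(drop=True), issues=issues)


def write_peptide_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def read_fasta(path) -> Dict[str, str]:
    """FASTA → ``{id: sequence}``; the id is the first whitespace-delimited
    header token. Empty files and duplicate ids are errors."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(proteome: Dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for pid in proteome:
            fh.write(f">{pid}\n")
            seq = proteome[pid]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def accession(fasta_id: str) -> str:
    """UniProt-style accession from a FASTA id: ``sp|P01112|RASH_HUMAN`` →
    ``P01112``; ids without pipes are returned unchanged."""
    parts = fasta_id.split("|")
    return parts[1] if len(parts) >= 2 else fasta_id


def read_rank_table(path) -> pd.DataFrame:
    """External predictor output: ``peptide,allele,score,percentile_rank``
    (allele and score optional)."""
    frame = pd.read_csv(path, dtype={"peptide": str})
    if "peptide" not in frame.columns or "percentile_rank" not in frame.columns:
        raise FormatError(
            f"{path}: need 'peptide' and 'percentile_rank' columns, "
            f"got {list(frame.columns)}"
        )
    return frame


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable config."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_manifest(out_dir, command: str, inputs: Dict, seed: Optional[int], config: Dict) -> Path:
    """Write the JSON run manifest next to a command's outputs."""
    from appm import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "seed": seed,
        "config": config,
        "config_hash": config_hash(config),
        "versions": {
            "appm": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
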