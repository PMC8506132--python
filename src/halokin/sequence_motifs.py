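"""Wildcard-aware scanning for conserved loop motifs in protein sequences.

Halobacterial SDR-family glucose-6-phosphate dehydrogenases carry two short
conserved motifs in the substrate-binding region: NLTX2H (written here as
the pattern ``NLTXXH``, where X matches any residue) on the beta6-alpha10
loop, and YERG near the phosphate-binding arginine.  This module reads
FASTA and reports every (possibly overlapping) match with 1-based start
positions so hits line up with residue numbering.
"""

from __future__ import annotations

import io
import re
import warnings
from typing import NamedTuple

import pandas as pd
from Bio import SeqIO

from .errors import FastaFormatError, InvalidParameterError

__all__ = ["MotifHit", "AMINO_ACIDS", "read_fasta", "scan_motif", "scan_fasta",
           "write_motif_tsv"]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
WILDCARD = "X"


class MotifHit(NamedTuple):
    """One motif occurrence: sequence id, 1-based start, matched substring."""

    sequence_id: str
    start: int
    matched: str


def read_fasta(text: str) -> list[tuple[str, str]]:
    """Parse FASTA text into (id, sequence) pairs.

    Sequences are uppercased, whitespace-joined and stripped of '*'
    terminators.  Records with empty sequences are skipped with a warning;
    input without a '>' header is a format error.
    """
    if not text or not text.strip():
        raise FastaFormatError("empty FASTA input")
    if text.lstrip()[0] != ">":
        raise FastaFormatError("FASTA input must start with a '>' header")
    out = []
    for record in SeqIO.parse(io.StringIO(text), "fasta"):
        seq = str(record.seq).upper().replace("*", "").replace(" ", "")
        if not seq:
            warnings.warn(
                f"FASTA record {record.id!r} has an empty sequence; skipped",
                stacklevel=2,
            )
            continue
        out.append((record.id, seq))
    return out


def _compile(pattern: str) -> re.Pattern:
    pattern = pattern.upper()
    bad = sorted(set(pattern) - AMINO_ACIDS - {WILDCARD})
    if bad:
        raise InvalidParameterError(
            f"illegal pattern characters {bad}; use one-letter amino-acid "
            f"codes and '{WILDCARD}' as wildcard"
        )
    # lookahead so that overlapping matches are all reported
    body = "".join("." if c == WILDCARD else re.escape(c) for c in pattern)
    return re.compile(f"(?=({body}))")


def scan_motif(sequence: str, pattern: str, sequence_id: str = "") -> list[MotifHit]:
    """All (overlapping) occurrences of ``pattern`` in ``sequence``.

    'X' matches any residue; matching is case-insensitive; start positions
    are 1-based to align with residue numbering.
    """
    rx = _compile(pattern)
    seq = sequence.upper()
    return [
        MotifHit(sequence_id=sequence_id, start=m.start() + 1, matched=m.group(1))
        for m in rx.finditer(seq)
    ]


def scan_fasta(records: list[tuple[str, str]], pattern: str) -> list[MotifHit]:
    """Scan every record of a parsed FASTA for the pattern."""
    hits = []
    for seq_id, seq in records:
        hits.extend(scan_motif(seq, pattern, sequence_id=seq_id))
    return hits


def write_motif_tsv(hits: list[MotifHit], pattern: str, path) -> None:
    """TSV columns: seq_id,start,matched,pattern."""
    pd.DataFrame(
        [
            {"seq_id": h.sequence_id, "start": h.start, "matched": h.matched,
             "pattern": pattern.upper()}
            for h in hits
        ],
        columns=["seq_id", "start", "matched", "pattern"],
    ).to_csv(path, sep="\t", index=False)
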