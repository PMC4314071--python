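"""Reading and normalising genome FASTA and GFF3 annotation files.

Coordinates are kept 1-based inclusive everywhere in this package, matching
the GFF3 convention, so annotation coordinates can be echoed unchanged into
the output tables.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Iterable, Mapping
from urllib.parse import unquote

from Bio import SeqIO

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

#: Characters considered ordinary after normalisation; anything else is kept
#: verbatim but reported once per chromosome (resequenced strains carry
#: ambiguity codes and silently rewriting them would corrupt designs).
VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class ChromosomeRecord:
    """One named DNA sequence.

    ``id`` is the first whitespace-delimited token of the FASTA header;
    ``length`` is always counted from the concatenated sequence body, never
    trusted from header text.
    """

    id: str
    sequence: str
    length: int

    def __post_init__(self) -> None:
        if self.length != len(self.sequence):
            raise ValueError("length must equal len(sequence)")


@dataclass(frozen=True)
class AnnotationRecord:
    """One raw GFF3 feature line.

    ``start``/``end`` are 1-based inclusive.  ``strand`` is normalised to
    '+' or '-' where oriented; '.'/'?' are retained here and rejected later
    only if such a record is requested as a design target.
    """

    seqid: str
    source: str
    ftype: str
    start: int
    end: int
    strand: str
    attributes: Mapping[str, str] = field(default_factory=dict)


def read_fasta(path: str | Path) -> list[ChromosomeRecord]:
    """Parse a (possibly line-wrapped, multi-record) FASTA file.

    Raises
    ------
    ParseError
        If the file is empty, does not begin with a ``>`` header after
        optional blank lines, or contains duplicate chromosome ids.
    """
    path = Path(path)
    text = path.read_text().lstrip("\n\r \t")
    if not text:
        raise ParseError(f"{path}: empty FASTA file")
    if not text.startswith(">"):
        raise ParseError(f"{path}: not a FASTA file (first non-blank line lacks '>')")

    records: list[ChromosomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(StringIO(text), "fasta"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate chromosome id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        odd = Counter(c for c in seq if c not in VALID_BASES)
        if odd:
            logger.warning(
                "chromosome %s: %d non-ACGTN characters kept verbatim (%s)",
                rec.id,
                sum(odd.values()),
                ", ".join(f"{c}x{n}" for c, n in sorted(odd.items())),
            )
        records.append(ChromosomeRecord(id=rec.id, sequence=seq, length=len(seq)))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ChromosomeRecord], path: str | Path, width: int = 60) -> None:
    """Write records back out, wrapping sequence lines at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.sequence[i : i + width] + "\n")


def _parse_attributes(column: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in column.split(";"):
        item = item.strip()
        if not item:
            continue
        key, _, value = item.partition("=")
        attrs[key] = unquote(value)
    return attrs


def read_annotation(path: str | Path) -> list[AnnotationRecord]:
    """Parse a 9-column GFF3 file into raw annotation records.

    Lines beginning ``#`` are skipped; parsing stops at a ``##FASTA``
    directive.  Malformed lines (fewer than 8 columns, non-integer or
    inverted coordinates) are fatal and reported with their line number.
    """
    path = Path(path)
    records: list[AnnotationRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("##FASTA"):
                break
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 8:
                raise ParseError(
                    f"{path}:{lineno}: expected >= 8 tab-delimited columns, got {len(cols)}"
                )
            seqid, source, ftype, start_s, end_s, _score, strand, _frame = cols[:8]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinates {start_s!r}..{end_s!r}"
                ) from None
            if not 1 <= start <= end:
                raise ParseError(f"{path}:{lineno}: invalid span {start}..{end}")
            if strand == "−":  # unicode minus occasionally survives copy/paste
                strand = "-"
            attrs = _parse_attributes(cols[8]) if len(cols) > 8 else {}
            records.append(
                AnnotationRecord(
                    seqid=seqid,
                    source=source,
                    ftype=ftype,
                    start=start,
                    end=end,
                    strand=strand,
                    attributes=attrs,
                )
            )
    return records


def genome_index(records: Iterable[ChromosomeRecord]) -> dict[str, ChromosomeRecord]:
    """Index chromosomes by id for O(1) lookup during design."""
    return {rec.id: rec for rec in records}


def validate_pairing(
    chromosomes: Iterable[ChromosomeRecord], records: Iterable[AnnotationRecord]
) -> None:
    """Check every annotation seqid resolves to a loaded chromosome.

    Raises :class:`ValidationError` before any design work begins if the
    two files do not belong together.
    """
    known = {rec.id for rec in chromosomes}
    missing = sorted({rec.seqid for rec in records} - known)
    if missing:
        raise ValidationError(
            "annotation references chromosomes absent from the genome: " + ", ".join(missing)
        )
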