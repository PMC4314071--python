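"""Build a catalog of design targets from raw annotation records.

Multi-segment CDSs (intron-containing genes) are merged to their outermost
genomic envelope: deletion cassettes replace the whole locus, so design
geometry is defined on genomic, not spliced, coordinates.  Multi-transcript
genes contribute exactly one catalog entry, taken from the transcript whose
ID sorts first lexicographically.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .genome_io import AnnotationRecord, ChromosomeRecord

logger = logging.getLogger(__name__)

#: Canonical feature codes and the annotation "type" strings they match by
#: default.  Extra aliases (e.g. pseudogene types treated as genes) are
#: opt-in via configuration.
FEATURE_TYPES: dict[str, tuple[str, ...]] = {
    "CDS": ("CDS",),
    "ncRNA": ("ncRNA",),
    "3UTR": ("three_prime_UTR", "3'UTR", "3UTR"),
    "tRNA": ("tRNA",),
}

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True, order=True)
class GenomicFeature:
    """One catalogued design target (1-based inclusive span, oriented)."""

    chrom_id: str
    start: int
    end: int
    systematic_name: str
    common_name: str
    strand: str
    ftype: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.systematic_name}: start > end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.systematic_name}: strand must be '+' or '-'")

    @property
    def span_length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ValidationNote:
    """A soft warning about a CDS that violates start/stop conventions."""

    feature: str
    kind: str  # one of {no_ATG_start, no_stop_end, other}
    detail: str

    _KINDS = frozenset({"no_ATG_start", "no_stop_end", "other"})

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown note kind {self.kind!r}")


def _top_ancestor(node: str, parent_of: Mapping[str, str]) -> str:
    """Follow Parent links to the top-level (gene) identifier."""
    seen = {node}
    while node in parent_of:
        node = parent_of[node]
        if node in seen:  # defensive: cyclic annotation
            break
        seen.add(node)
    return node


def build_catalog(
    records: Iterable[AnnotationRecord],
    ftype: str,
    type_aliases: Sequence[str] = (),
) -> list[GenomicFeature]:
    """Catalog every target of the requested feature type.

    Parameters
    ----------
    records
        All parsed annotation records (the full file, so parent/child links
        between genes, transcripts and segments can be resolved).
    ftype
        Canonical feature code: ``CDS``, ``ncRNA``, ``3UTR`` or ``tRNA``.
    type_aliases
        Extra annotation "type" strings to treat as matches, e.g.
        ``("pseudogene",)`` when pseudogenes should be catalogued as genes.

    Returns
    -------
    list of GenomicFeature sorted by (chromosome, start, systematic name).
    """
    if ftype not in FEATURE_TYPES:
        raise ValueError(f"unknown feature code {ftype!r}")
    match_types = set(FEATURE_TYPES[ftype]) | set(type_aliases)

    records = list(records)
    parent_of: dict[str, str] = {}
    name_of: dict[str, str] = {}
    for rec in records:
        rid = rec.attributes.get("ID")
        if rid is None:
            continue
        parent = rec.attributes.get("Parent")
        if parent:
            parent_of[rid] = parent.split(",")[0]
        if "Name" in rec.attributes:
            name_of[rid] = rec.attributes["Name"]

    # gene id -> transcript id -> member records
    groups: dict[str, dict[str, list[AnnotationRecord]]] = defaultdict(lambda: defaultdict(list))
    for rec in records:
        if rec.ftype not in match_types:
            continue
        tid = rec.attributes.get("Parent", rec.attributes.get("ID"))
        if tid is None:
            tid = f"{rec.seqid}:{rec.start}-{rec.end}({rec.strand})"
        tid = tid.split(",")[0]
        gene = _top_ancestor(tid, parent_of)
        groups[gene][tid].append(rec)

    features: list[GenomicFeature] = []
    for gene, transcripts in groups.items():
        chosen = min(transcripts)
        if len(transcripts) > 1:
            dropped = sorted(set(transcripts) - {chosen})
            logger.info(
                "%s: multiple transcripts; using %s, dropping %s",
                gene, chosen, ", ".join(dropped),
            )
        members = transcripts[chosen]
        chroms = {r.seqid for r in members}
        strands = {r.strand for r in members}
        if len(chroms) > 1 or len(strands) > 1:
            logger.error(
                "%s: segments span multiple chromosomes/strands; skipped", gene
            )
            continue
        strand = strands.pop()
        if strand not in {"+", "-"}:
            logger.warning("%s: strand %r is unoriented; skipped", gene, strand)
            continue
        common = name_of.get(gene) or next(
            (r.attributes["Name"] for r in members if "Name" in r.attributes), ""
        )
        features.append(
            GenomicFeature(
                chrom_id=chroms.pop(),
                start=min(r.start for r in members),
                end=max(r.end for r in members),
                systematic_name=gene,
                common_name=common,
                strand=strand,
                ftype=ftype,
            )
        )
    features.sort(key=lambda f: (f.chrom_id, f.start, f.systematic_name))
    return features


def feature_sense_sequence(
    genome: Mapping[str, ChromosomeRecord], feature: GenomicFeature
) -> str:
    """The feature's sequence read 5'->3' in its direction of transcription."""
    chrom = genome[feature.chrom_id]
    plus = chrom.sequence[feature.start - 1 : feature.end]
    return plus if feature.strand == "+" else str(Seq(plus).reverse_complement())


def validate_feature(
    feature: GenomicFeature, genome: Mapping[str, ChromosomeRecord]
) -> list[ValidationNote]:
    """Check a CDS against the ATG-start / stop-end conventions.

    Returns advisory notes only; violations (pseudogenes, annotation quirks)
    never block primer design.
    """
    notes: list[ValidationNote] = []
    sense = feature_sense_sequence(genome, feature)
    if len(sense) < 6:
        notes.append(
            ValidationNote(feature.systematic_name, "other", f"span only {len(sense)} bp")
        )
        return notes
    if sense[:3] != "ATG":
        notes.append(
            ValidationNote(
                feature.systematic_name, "no_ATG_start", f"sense sequence begins {sense[:3]}"
            )
        )
    if sense[-3:] not in STOP_CODONS:
        notes.append(
            ValidationNote(
                feature.systematic_name, "no_stop_end", f"final triplet is {sense[-3:]}"
            )
        )
    return notes
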