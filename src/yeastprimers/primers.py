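"""Long-primer design for deletion and C-terminal tagging cassettes.

The geometry, for a target of homology length N (all positions in sense
space, i.e. read in the feature's direction of transcription):

* deletion forward, CDS:        N-3 bp upstream flank + the start codon
* deletion forward, non-coding: N bp upstream flank
* C-tag forward (CDS only):     the N bp immediately 5' of the stop codon
* reverse (shared by both):     reverse complement of (stop codon + N-3 bp
  downstream flank) for CDSs, of the N bp downstream flank otherwise

Untailed homology arms always have length exactly N; flanks that run off a
chromosome end are padded with 'N' so the length contract never breaks.
Constant 3' tails are the pFA6a-vector priming sites.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

from .catalog import GenomicFeature
from .errors import DesignError
from .genome_io import ChromosomeRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_SUPPORTED = re.compile(r"[^ACGTN]")


@dataclass(frozen=True)
class TailSet:
    """Constant 3' priming-site extensions appended to the homology arms.

    ``fwd_tail`` and ``rev_tail`` hybridise to the multi-cloning site flanks
    of pFA6a-series vectors; ``utr_fwd_tail`` primes the adh1 terminator on
    the same vectors and replaces the standard forward tail when deleting
    3'UTRs (so the upstream gene keeps a terminator).
    """

    fwd_tail: str = "CGGATCCCCGGGTTAATTAA"
    rev_tail: str = "GAATTCGAGCTCGTTTAAAC"
    utr_fwd_tail: str = "GCGAATTTCTTATGATTTATG"

    def __post_init__(self) -> None:
        for name in ("fwd_tail", "rev_tail", "utr_fwd_tail"):
            seq = getattr(self, name)
            if not seq or _SUPPORTED.search(seq):
                raise DesignError(f"tail {name} must be non-empty DNA over ACGTN")


DEFAULT_TAILS = TailSet()


@dataclass(frozen=True)
class DesignParams:
    """Tunable design parameters.

    homology_length
        N, the homology arm length in bp.  80 is conventional for S. pombe,
        50 for S. cerevisiae.  Must be >= 4 so the CDS N-3 geometry leaves
        at least one upstream base.
    ftype
        Canonical feature code: CDS, ncRNA, 3UTR or tRNA.
    tailed
        Whether tailed variants are produced alongside the bare arms.
    """

    homology_length: int
    ftype: str = "CDS"
    tailed: bool = True

    def __post_init__(self) -> None:
        if self.homology_length < 4:
            raise DesignError("homology length N must be >= 4 (N-3 upstream bases for CDSs)")
        if self.ftype not in {"CDS", "ncRNA", "3UTR", "tRNA"}:
            raise DesignError(f"unknown feature code {self.ftype!r}")


@dataclass(frozen=True)
class PrimerSet:
    """All primers designed for one feature, tailed and untailed."""

    feature: GenomicFeature
    fwd_del: str
    fwd_del_tailed: str
    fwd_tag: Optional[str]
    fwd_tag_tailed: Optional[str]
    rev: str
    rev_tailed: str
    overlap_names: tuple[str, ...] = field(default_factory=tuple)
    overlap_count: int = 0

    def with_overlaps(self, names: Sequence[str]) -> "PrimerSet":
        return replace(self, overlap_names=tuple(names), overlap_count=len(names))


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over {A,C,G,T,N} (N maps to N)."""
    bad = _SUPPORTED.search(seq)
    if bad:
        raise DesignError(
            f"unsupported character {bad.group()!r} at position {bad.start() + 1}"
        )
    return seq.translate(_COMPLEMENT)[::-1]


def _fetch_plus(chrom: ChromosomeRecord, start: int, end: int) -> str:
    """Plus-strand bases start..end (1-based inclusive), 'N'-padded beyond ends."""
    if start > end:
        return ""
    left = max(0, 1 - start)
    right = max(0, end - chrom.length)
    core = chrom.sequence[max(start, 1) - 1 : min(end, chrom.length)]
    return "N" * left + core + "N" * right


def _chromosome(genome: Mapping[str, ChromosomeRecord], feature: GenomicFeature) -> ChromosomeRecord:
    try:
        return genome[feature.chrom_id]
    except KeyError:
        raise DesignError(
            f"{feature.systematic_name}: chromosome {feature.chrom_id!r} not loaded"
        ) from None


def sense_flank(
    genome: Mapping[str, ChromosomeRecord],
    feature: GenomicFeature,
    side: str,
    length: int,
) -> str:
    """Flanking sequence of the feature in sense orientation.

    ``side`` is ``upstream`` (5' of the feature in transcription direction)
    or ``downstream``.  Exactly ``length`` characters are returned; positions
    beyond either chromosome end are the padding character 'N'.
    """
    if side not in {"upstream", "downstream"}:
        raise ValueError("side must be 'upstream' or 'downstream'")
    if length < 0:
        raise ValueError("flank length must be >= 0")
    chrom = _chromosome(genome, feature)
    five_prime = (side == "upstream") == (feature.strand == "+")
    if five_prime:
        segment = _fetch_plus(chrom, feature.start - length, feature.start - 1)
    else:
        segment = _fetch_plus(chrom, feature.end + 1, feature.end + length)
    return segment if feature.strand == "+" else reverse_complement(segment)


def _sense_start_codon(genome: Mapping[str, ChromosomeRecord], feature: GenomicFeature) -> str:
    chrom = _chromosome(genome, feature)
    if feature.strand == "+":
        return _fetch_plus(chrom, feature.start, feature.start + 2)
    return reverse_complement(_fetch_plus(chrom, feature.end - 2, feature.end))


def _sense_stop_codon(genome: Mapping[str, ChromosomeRecord], feature: GenomicFeature) -> str:
    chrom = _chromosome(genome, feature)
    if feature.strand == "+":
        return _fetch_plus(chrom, feature.end - 2, feature.end)
    return reverse_complement(_fetch_plus(chrom, feature.start, feature.start + 2))


def design_deletion_forward(
    feature: GenomicFeature,
    genome: Mapping[str, ChromosomeRecord],
    params: DesignParams,
) -> str:
    """Forward deletion homology arm (length exactly N).

    CDS mode ends with the sense start codon; non-coding modes are the N bp
    immediately upstream of the feature.
    """
    n = params.homology_length
    if params.ftype == "CDS":
        arm = sense_flank(genome, feature, "upstream", n - 3) + _sense_start_codon(genome, feature)
    else:
        arm = sense_flank(genome, feature, "upstream", n)
    assert len(arm) == n
    return arm


def design_ctag_forward(
    feature: GenomicFeature,
    genome: Mapping[str, ChromosomeRecord],
    params: DesignParams,
) -> str:
    """C-terminal tagging forward arm: the N sense bp just 5' of the stop codon.

    For features shorter than N+3 the arm extends into genomic context
    upstream of the feature start; padding only occurs at chromosome ends.
    """
    if feature.ftype != "CDS":
        raise DesignError("C-terminal tagging is defined for CDS features only")
    n = params.homology_length
    chrom = _chromosome(genome, feature)
    if feature.strand == "+":
        arm = _fetch_plus(chrom, feature.end - 2 - n, feature.end - 3)
    else:
        arm = reverse_complement(_fetch_plus(chrom, feature.start + 3, feature.start + 2 + n))
    assert len(arm) == n
    return arm


def design_reverse(
    feature: GenomicFeature,
    genome: Mapping[str, ChromosomeRecord],
    params: DesignParams,
) -> str:
    """Reverse arm shared by deletion and tagging (length exactly N).

    CDS mode: reverse complement of (stop codon + N-3 bp downstream flank).
    Non-coding modes: reverse complement of the N bp downstream flank.
    """
    n = params.homology_length
    if params.ftype == "CDS":
        sense = _sense_stop_codon(genome, feature) + sense_flank(
            genome, feature, "downstream", n - 3
        )
    else:
        sense = sense_flank(genome, feature, "downstream", n)
    arm = reverse_complement(sense)
    assert len(arm) == n
    return arm


def attach_tail(homology: str, mode: str, tails: TailSet = DEFAULT_TAILS) -> str:
    """Append the constant vector priming site at the 3' end of an arm."""
    if not homology:
        raise DesignError("homology arm must be non-empty")
    tail = {
        "fwd_standard": tails.fwd_tail,
        "fwd_utr": tails.utr_fwd_tail,
        "rev": tails.rev_tail,
    }.get(mode)
    if tail is None:
        raise ValueError(f"unknown tail mode {mode!r}")
    return homology + tail


def design_primer_set(
    feature: GenomicFeature,
    genome: Mapping[str, ChromosomeRecord],
    params: DesignParams,
    tails: TailSet = DEFAULT_TAILS,
) -> PrimerSet:
    """Design the complete primer set for one feature."""
    fwd = design_deletion_forward(feature, genome, params)
    fwd_mode = "fwd_utr" if params.ftype == "3UTR" else "fwd_standard"
    rev = design_reverse(feature, genome, params)
    if params.ftype == "CDS":
        tag = design_ctag_forward(feature, genome, params)
        tag_tailed = attach_tail(tag, "fwd_standard", tails)
    else:
        tag = tag_tailed = None
    return PrimerSet(
        feature=feature,
        fwd_del=fwd,
        fwd_del_tailed=attach_tail(fwd, fwd_mode, tails),
        fwd_tag=tag,
        fwd_tag_tailed=tag_tailed,
        rev=rev,
        rev_tailed=attach_tail(rev, "rev", tails),
    )
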