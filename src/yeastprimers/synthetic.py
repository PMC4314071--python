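"""Seeded synthetic genome + annotation generator with a primer truth table.

Every other module is testable without downloading real genomes: this module
plants ORFs (ATG + sense codons + stop) on both strands of random background
sequence, emits standard FASTA/GFF3 text, and computes the expected primers
for each planted feature with a brute-force oracle that shares no code with
the design engine.

The oracle works in "window space": it extracts the feature span plus N bp
on each side from the plus strand (padding with 'N' beyond chromosome ends),
reverse-complements the whole window for minus-strand features, and then
takes primers as plain substrings of that sense window.  The design engine
instead fetches each flank separately in genomic coordinates, so agreement
between the two is a genuine cross-check of the indexing arithmetic.

The generated plan always includes the awkward cases real annotations
contain: minus-strand genes, a multi-segment (intron-containing) CDS on each
strand, a nested antisense gene pair, a multi-transcript gene, overlapping
ncRNAs, a gene starting at base 1 of a chromosome and a gene flush with a
chromosome end.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FixtureError

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = tuple(
    "".join(c) for c in itertools.product("ACGT", repeat=3) if "".join(c) not in _STOPS
)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: GFF3 type string emitted per feature code.
_GFF_TYPE = {"CDS": "CDS", "ncRNA": "ncRNA", "3UTR": "three_prime_UTR", "tRNA": "tRNA"}


def _rc(seq: str) -> str:
    # oracle-local reverse complement; deliberately not shared with primers.py
    return "".join(_COMP[b] for b in reversed(seq))


@dataclass(frozen=True)
class PlannedFeature:
    """One feature to plant: annotation lines plus (for CDSs) sense sequence."""

    name: str
    code: str  # CDS | ncRNA | 3UTR | tRNA
    chrom: str
    strand: str
    segments: tuple[tuple[int, int], ...]  # 1-based inclusive, ascending
    common_name: str = ""
    sense_seq: Optional[str] = None  # written into the genome when set
    allow_overwrite: bool = False  # nested genes overwrite their host's interior
    decoy_transcripts: tuple[tuple[str, tuple[tuple[int, int], ...]], ...] = ()

    @property
    def start(self) -> int:
        return min(s for s, _ in self.segments)

    @property
    def end(self) -> int:
        return max(e for _, e in self.segments)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic genome.

    With ``plan=None`` a plan of ``n_features`` features is generated from
    ``seed``; an explicit plan (with ``chrom_lengths``) gives full control
    and lets tests construct deliberately infeasible layouts.
    """

    seed: int = 0
    n_features: int = 40
    homology_lengths: tuple[int, ...] = (4, 6, 50, 80)
    plan: Optional[tuple[PlannedFeature, ...]] = None
    chrom_lengths: Optional[dict[str, int]] = None


@dataclass
class SyntheticGenome:
    """Generated genome: file texts, final sequences and the truth table."""

    fasta_text: str
    gff3_text: str
    sequences: dict[str, str]
    features: tuple[PlannedFeature, ...]
    truth: pd.DataFrame  # one row per (feature, N)

    def write(self, directory: str | Path) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": directory / "genome.fa",
            "gff3": directory / "annotation.gff3",
            "truth": directory / "truth.tsv",
        }
        paths["fasta"].write_text(self.fasta_text)
        paths["gff3"].write_text(self.gff3_text)
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


# ---------------------------------------------------------------------------
# brute-force primer oracle


def _padded_plus(seq: str, lo: int, hi: int) -> str:
    if lo > hi:
        return ""
    left = "N" * max(0, 1 - lo)
    right = "N" * max(0, hi - len(seq))
    return left + seq[max(lo, 1) - 1 : min(hi, len(seq))] + right


def oracle_primers(
    sequences: dict[str, str],
    chrom: str,
    start: int,
    end: int,
    strand: str,
    code: str,
    n: int,
) -> dict[str, Optional[str]]:
    """Expected primers by direct substring extraction from a sense window."""
    window = _padded_plus(sequences[chrom], start - n, end + n)
    if strand == "-":
        window = _rc(window)
    length = end - start + 1
    if code == "CDS":
        fwd = window[3 : n + 3]
        tag = window[length - 3 : n + length - 3]
        rev = _rc(window[n + length - 3 : 2 * n + length - 3])
    else:
        fwd = window[0:n]
        tag = None
        rev = _rc(window[n + length : 2 * n + length])
    return {"fwd_del": fwd, "fwd_tag": tag, "rev": rev, "sense": window[n : n + length]}


# ---------------------------------------------------------------------------
# plan generation


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = "".join(rng.choice(_NONSTOP_CODONS, size=n_codons))
    return "ATG" + body + str(rng.choice(_STOPS))


def _auto_plan(spec: FixtureSpec) -> tuple[tuple[PlannedFeature, ...], dict[str, int]]:
    rng = np.random.default_rng(spec.seed)
    chrom_names = ("chrI", "chrII", "chrIII")
    cursors = {c: 0 for c in chrom_names}
    plan: list[PlannedFeature] = []

    def place(chrom: str, length: int, gap: int) -> tuple[int, int]:
        start = cursors[chrom] + gap + 1
        end = start + length - 1
        cursors[chrom] = end
        return start, end

    counter = itertools.count(1)

    def sysname(code: str) -> str:
        return f"SYN{code}{next(counter):04d}"

    # case: gene starting at base 1 (upstream flank fully padded)
    seq = _random_cds(rng, 12)
    plan.append(
        PlannedFeature(
            name=sysname("G"), code="CDS", chrom="chrI", strand="+",
            segments=((1, len(seq)),), sense_seq=seq, common_name="edg1",
        )
    )
    cursors["chrI"] = len(seq)

    n_bulk = max(spec.n_features - 2, 0)  # two slots reserved for the end cases
    for i in range(n_bulk):
        chrom = chrom_names[i % len(chrom_names)]
        strand = "+" if rng.random() < 0.5 else "-"
        gap = int(rng.integers(30, 200))
        if i == 2 or i == 5:  # multi-segment CDS, one per strand
            strand = "+" if i == 2 else "-"
            n_codons = int(rng.integers(20, 40))
            seq = _random_cds(rng, n_codons)
            start, end = place(chrom, len(seq), gap)
            intron = int(rng.integers(20, 40))
            cut = start + int(rng.integers(6, len(seq) - intron - 6))
            segments = ((start, cut), (cut + intron + 1, end))
            plan.append(
                PlannedFeature(
                    name=sysname("G"), code="CDS", chrom=chrom, strand=strand,
                    segments=segments, sense_seq=seq,
                )
            )
        elif i == 4:  # nested antisense pair: inner gene inside the outer's interior
            outer_seq = _random_cds(rng, 60)
            o_start, o_end = place(chrom, len(outer_seq), gap)
            plan.append(
                PlannedFeature(
                    name=sysname("G"), code="CDS", chrom=chrom, strand="+",
                    segments=((o_start, o_end),), sense_seq=outer_seq, common_name="hst1",
                )
            )
            inner_seq = _random_cds(rng, 20)
            i_start = o_start + 12
            plan.append(
                PlannedFeature(
                    name=sysname("G"), code="CDS", chrom=chrom, strand="-",
                    segments=((i_start, i_start + len(inner_seq) - 1),),
                    sense_seq=inner_seq, allow_overwrite=True, common_name="nst1",
                )
            )
        elif i == 6:  # multi-transcript gene: decoy transcript .2 annotated only
            seq = _random_cds(rng, 30)
            start, end = place(chrom, len(seq), gap)
            plan.append(
                PlannedFeature(
                    name=sysname("G"), code="CDS", chrom=chrom, strand=strand,
                    segments=((start, end),), sense_seq=seq,
                    decoy_transcripts=((".2", ((start + 9, end),)),),
                )
            )
        elif i % 7 == 3:  # ncRNA over background; every other one overlaps its predecessor
            length = int(rng.integers(80, 300))
            start, end = place(chrom, length, gap)
            plan.append(
                PlannedFeature(
                    name=sysname("N"), code="ncRNA", chrom=chrom, strand=strand,
                    segments=((start, end),),
                )
            )
            if i % 14 == 3:
                o_start = start + length // 2
                o_end = o_start + int(rng.integers(60, 200))
                cursors[chrom] = max(cursors[chrom], o_end)
                plan.append(
                    PlannedFeature(
                        name=sysname("N"), code="ncRNA", chrom=chrom,
                        strand="-" if strand == "+" else "+",
                        segments=((o_start, o_end),),
                    )
                )
        elif i % 11 == 4:  # tRNA over background
            length = int(rng.integers(70, 90))
            start, end = place(chrom, length, gap)
            plan.append(
                PlannedFeature(
                    name=sysname("T"), code="tRNA", chrom=chrom, strand=strand,
                    segments=((start, end),),
                )
            )
        elif i % 13 == 5:  # 3'UTR over background
            length = int(rng.integers(50, 250))
            start, end = place(chrom, length, gap)
            plan.append(
                PlannedFeature(
                    name=sysname("U"), code="3UTR", chrom=chrom, strand=strand,
                    segments=((start, end),),
                )
            )
        else:  # ordinary CDS
            seq = _random_cds(rng, int(rng.integers(8, 60)))
            start, end = place(chrom, len(seq), gap)
            common = f"syn{i}" if rng.random() < 0.3 else ""
            plan.append(
                PlannedFeature(
                    name=sysname("G"), code="CDS", chrom=chrom, strand=strand,
                    segments=((start, end),), sense_seq=seq, common_name=common,
                )
            )

    # case: minus-strand gene flush with the chrI end (downstream flank padded)
    seq = _random_cds(rng, 15)
    start, end = place("chrI", len(seq), int(rng.integers(40, 120)))
    plan.append(
        PlannedFeature(
            name=sysname("G"), code="CDS", chrom="chrI", strand="-",
            segments=((start, end),), sense_seq=seq, common_name="edg2",
        )
    )
    chrom_lengths = {
        c: cursors[c] + (0 if c == "chrI" else int(rng.integers(60, 300)))
        for c in chrom_names
    }
    return tuple(plan), chrom_lengths


# ---------------------------------------------------------------------------
# materialisation


def _plant(spec: FixtureSpec, plan: Sequence[PlannedFeature], lengths: dict[str, int]) -> dict[str, str]:
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    arrays = {c: rng.choice(_BASES, size=n) for c, n in lengths.items()}
    written = {c: np.zeros(n, dtype=bool) for c, n in lengths.items()}
    for feat in plan:
        if feat.sense_seq is None:
            if feat.end > lengths[feat.chrom]:
                raise FixtureError(f"{feat.name}: span exceeds chromosome {feat.chrom}")
            continue
        span = feat.end - feat.start + 1
        if len(feat.sense_seq) != span:
            raise FixtureError(f"{feat.name}: sense sequence length != span")
        if feat.start < 1 or feat.end > lengths[feat.chrom]:
            raise FixtureError(f"{feat.name}: span outside chromosome {feat.chrom}")
        plus = feat.sense_seq if feat.strand == "+" else _rc(feat.sense_seq)
        sl = slice(feat.start - 1, feat.end)
        if written[feat.chrom][sl].any() and not feat.allow_overwrite:
            raise FixtureError(
                f"infeasible plan: {feat.name} overwrites previously planted sequence"
            )
        arrays[feat.chrom][sl] = list(plus)
        written[feat.chrom][sl] = True
    return {c: "".join(a) for c, a in arrays.items()}


def _gff3_lines(plan: Sequence[PlannedFeature]) -> str:
    lines = ["##gff-version 3"]
    src = "synthetic"
    for feat in plan:
        gff_type = _GFF_TYPE[feat.code]
        name_attr = f";Name={feat.common_name}" if feat.common_name else ""
        if feat.code == "CDS":
            lines.append(
                f"{feat.chrom}\t{src}\tgene\t{feat.start}\t{feat.end}\t.\t{feat.strand}\t."
                f"\tID={feat.name}{name_attr}"
            )
            transcripts = [(".1", feat.segments), *feat.decoy_transcripts]
            for suffix, segments in transcripts:
                tid = feat.name + suffix
                t_start = min(s for s, _ in segments)
                t_end = max(e for _, e in segments)
                lines.append(
                    f"{feat.chrom}\t{src}\tmRNA\t{t_start}\t{t_end}\t.\t{feat.strand}\t."
                    f"\tID={tid};Parent={feat.name}"
                )
                for k, (s, e) in enumerate(segments, start=1):
                    lines.append(
                        f"{feat.chrom}\t{src}\tCDS\t{s}\t{e}\t.\t{feat.strand}\t0"
                        f"\tID={tid}:cds:{k};Parent={tid}"
                    )
        else:
            (s, e), = feat.segments
            lines.append(
                f"{feat.chrom}\t{src}\t{gff_type}\t{s}\t{e}\t.\t{feat.strand}\t."
                f"\tID={feat.name}{name_attr}"
            )
    return "\n".join(lines) + "\n"


def _fasta_lines(sequences: dict[str, str], width: int = 60) -> str:
    out = []
    for name, seq in sequences.items():
        out.append(f">{name} synthetic")
        out.extend(seq[i : i + width] for i in range(0, len(seq), width))
    return "\n".join(out) + "\n"


def generate_synthetic_genome(spec: FixtureSpec) -> SyntheticGenome:
    """Generate a deterministic FASTA/GFF3 pair plus primer truth table."""
    if spec.plan is not None:
        if spec.chrom_lengths is None:
            raise FixtureError("explicit plans require chrom_lengths")
        plan, lengths = tuple(spec.plan), dict(spec.chrom_lengths)
    else:
        plan, lengths = _auto_plan(spec)
    sequences = _plant(spec, plan, lengths)

    rows = []
    for feat in plan:
        for n in spec.homology_lengths:
            expected = oracle_primers(
                sequences, feat.chrom, feat.start, feat.end, feat.strand, feat.code, n
            )
            rows.append(
                {
                    "systematic_name": feat.name,
                    "common_name": feat.common_name,
                    "ftype": feat.code,
                    "chrom": feat.chrom,
                    "start": feat.start,
                    "end": feat.end,
                    "strand": feat.strand,
                    "N": n,
                    "sense_seq": expected["sense"],
                    "fwd_del": expected["fwd_del"],
                    "fwd_tag": expected["fwd_tag"] or "",
                    "rev": expected["rev"],
                }
            )
    truth = pd.DataFrame(rows)
    return SyntheticGenome(
        fasta_text=_fasta_lines(sequences),
        gff3_text=_gff3_lines(plan),
        sequences=sequences,
        features=plan,
        truth=truth,
    )
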