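"""End-to-end run: read -> catalog -> design -> overlap -> write."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import catalog as _catalog
from . import genome_io, overlaps, reports
from .primers import DEFAULT_TAILS, DesignParams, TailSet, design_primer_set

logger = logging.getLogger(__name__)

#: Legacy feature codes (second positional argument).
FEATURE_CODES = {1: "CDS", 2: "ncRNA", 3: "3UTR", 4: "tRNA"}

#: Conventional homology-arm lengths per organism.
ORGANISM_DEFAULT_N = {"pombe": 80, "cerevisiae": 50}


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration for one design run."""

    genome_path: Path
    annotation_path: Path
    feature_code: str  # CDS | ncRNA | 3UTR | tRNA
    homology_length: int
    out_prefix: Path
    genome_label: str = "custom"
    tails: TailSet = DEFAULT_TAILS
    cds_aliases: tuple[str, ...] = ()  # e.g. pseudogene types catalogued as genes
    target_aliases: tuple[str, ...] = ()  # extra type strings for the target catalog
    end_region_len: int = 30
    xlsx: bool = False


@dataclass(frozen=True)
class RunResult:
    """Paths and bookkeeping produced by a successful run."""

    paths: dict
    manifest: reports.RunManifest
    primersets: tuple
    validation_notes: tuple = field(default_factory=tuple)


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute one complete design run, writing the three-file output.

    All computation happens in memory before anything is written, so a
    fatal error never leaves a partial primer table behind.
    """
    chroms = genome_io.read_fasta(config.genome_path)
    records = genome_io.read_annotation(config.annotation_path)
    genome_io.validate_pairing(chroms, records)
    genome = genome_io.genome_index(chroms)

    target_aliases = config.target_aliases
    if config.feature_code == "CDS":
        target_aliases = tuple(dict.fromkeys((*target_aliases, *config.cds_aliases)))
    targets = _catalog.build_catalog(records, config.feature_code, target_aliases)

    # overlap universe: CDS + ncRNA catalogs, both strands
    if config.feature_code == "CDS":
        cds_universe = targets
    else:
        cds_universe = _catalog.build_catalog(records, "CDS", config.cds_aliases)
    ncrna_universe = (
        targets
        if config.feature_code == "ncRNA"
        else _catalog.build_catalog(records, "ncRNA")
    )
    index = overlaps.OverlapIndex([*cds_universe, *ncrna_universe])

    params = DesignParams(homology_length=config.homology_length, ftype=config.feature_code)
    notes = []
    primersets = []
    for feat in targets:
        if config.feature_code == "CDS":
            for note in _catalog.validate_feature(feat, genome):
                logger.warning("%s: %s (%s)", note.feature, note.kind, note.detail)
                notes.append(note)
        ps = design_primer_set(feat, genome, params, config.tails)
        report = index.neighbors(feat)
        primersets.append(ps.with_overlaps(report.neighbors))

    manifest = reports.RunManifest(
        genome_label=config.genome_label,
        feature_code=config.feature_code,
        homology_length=config.homology_length,
        chromosomes=tuple((c.id, c.length) for c in chroms),
        feature_count=len(primersets),
    )
    paths = reports.write_run_outputs(
        manifest,
        primersets,
        genome,
        config.out_prefix,
        end_region_len=config.end_region_len,
        xlsx=config.xlsx,
    )
    logger.info(
        "designed %d primer sets (%s, N=%d) -> %s",
        len(primersets),
        config.feature_code,
        config.homology_length,
        paths["primers"],
    )
    return RunResult(
        paths=paths,
        manifest=manifest,
        primersets=tuple(primersets),
        validation_notes=tuple(notes),
    )
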