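"""Three-file output contract: header, primer database and check file.

All three are tab-delimited, Excel-importable UTF-8 text.  Coordinates are
echoed unchanged from the annotation (1-based inclusive).  An optional XLSX
export mirrors the primer table on a sheet named after the feature type.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .catalog import feature_sense_sequence
from .errors import ReportError
from .genome_io import ChromosomeRecord
from .primers import PrimerSet

PRIMER_COLUMNS = [
    "systematic_name",
    "common_name",
    "chromosome",
    "start",
    "end",
    "strand",
    "deletion_fwd",
    "deletion_fwd_tailed",
    "ctag_fwd",
    "ctag_fwd_tailed",
    "rev",
    "rev_tailed",
    "overlapping_features",
    "overlap_count",
]

CHECK_COLUMNS = ["systematic_name", "five_prime_region", "three_prime_region", "full_sequence"]


@dataclass(frozen=True)
class RunManifest:
    """Summary of one design run, written to the header file."""

    genome_label: str
    feature_code: str
    homology_length: int
    chromosomes: tuple[tuple[str, int], ...]  # (name, length) pairs
    feature_count: int


def write_header_file(manifest: RunManifest, path: str | Path) -> None:
    """Human-readable run summary: genome coordinates, feature count, schema."""
    lines = [
        f"Genome: {manifest.genome_label}",
        f"Feature type: {manifest.feature_code}",
        f"Homology length (bp): {manifest.homology_length}",
        f"Chromosomes: {len(manifest.chromosomes)}",
    ]
    lines += [f"  {name}\t{length}" for name, length in manifest.chromosomes]
    lines.append(f"Features analyzed: {manifest.feature_count}")
    lines.append("Primer table columns: " + ", ".join(PRIMER_COLUMNS))
    lines.append("Check file columns: " + ", ".join(CHECK_COLUMNS))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_header_file(path: str | Path) -> dict:
    """Re-parse a header file (used by tests and downstream bookkeeping)."""
    out: dict = {"chromosomes": []}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if line.startswith("  ") and "\t" in line:
            name, length = line.strip().split("\t")
            out["chromosomes"].append((name, int(length)))
        elif line.startswith("Genome: "):
            out["genome_label"] = line.removeprefix("Genome: ")
        elif line.startswith("Feature type: "):
            out["feature_code"] = line.removeprefix("Feature type: ")
        elif line.startswith("Homology length (bp): "):
            out["homology_length"] = int(line.rsplit(": ", 1)[1])
        elif line.startswith("Features analyzed: "):
            out["feature_count"] = int(line.rsplit(": ", 1)[1])
    return out


def primer_table_frame(primersets: Sequence[PrimerSet]) -> pd.DataFrame:
    """The primer database as a DataFrame (string-typed, blank for absent)."""
    names = [ps.feature.systematic_name for ps in primersets]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ReportError("duplicate systematic names: " + ", ".join(sorted(dupes)))
    rows = []
    for ps in primersets:
        f = ps.feature
        rows.append(
            {
                "systematic_name": f.systematic_name,
                "common_name": f.common_name,
                "chromosome": f.chrom_id,
                "start": str(f.start),
                "end": str(f.end),
                "strand": f.strand,
                "deletion_fwd": ps.fwd_del,
                "deletion_fwd_tailed": ps.fwd_del_tailed,
                "ctag_fwd": ps.fwd_tag or "",
                "ctag_fwd_tailed": ps.fwd_tag_tailed or "",
                "rev": ps.rev,
                "rev_tailed": ps.rev_tailed,
                "overlapping_features": ";".join(ps.overlap_names),
                "overlap_count": str(ps.overlap_count),
            }
        )
    return pd.DataFrame(rows, columns=PRIMER_COLUMNS, dtype=str)


def write_primer_table(primersets: Sequence[PrimerSet], path: str | Path) -> None:
    """Write the primer database: one header row plus one row per feature."""
    frame = primer_table_frame(primersets)
    frame.to_csv(path, sep="\t", index=False, quoting=csv.QUOTE_NONE, lineterminator="\n")


def read_primer_table(path: str | Path) -> pd.DataFrame:
    """Read a primer table back, preserving every field verbatim as text."""
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def write_check_file(
    primersets: Sequence[PrimerSet],
    genome: Mapping[str, ChromosomeRecord],
    path: str | Path,
    end_region_len: int = 30,
) -> None:
    """Per-feature 5'/3' end regions plus the full sense sequence.

    Intended for manual verification against a genome browser.  Features
    shorter than ``end_region_len`` report their full sequence as both end
    regions.
    """
    if end_region_len < 1:
        raise ReportError("end_region_len must be >= 1")
    rows = []
    for ps in primersets:
        sense = feature_sense_sequence(genome, ps.feature)
        rows.append(
            {
                "systematic_name": ps.feature.systematic_name,
                "five_prime_region": sense[:end_region_len],
                "three_prime_region": sense[-end_region_len:],
                "full_sequence": sense,
            }
        )
    frame = pd.DataFrame(rows, columns=CHECK_COLUMNS, dtype=str)
    frame.to_csv(path, sep="\t", index=False, quoting=csv.QUOTE_NONE, lineterminator="\n")


def export_xlsx(primersets: Sequence[PrimerSet], feature_code: str, path: str | Path) -> None:
    """Mirror the primer table on one spreadsheet sheet named by feature type."""
    from openpyxl import Workbook

    sheet_names = {"CDS": "CDS", "ncRNA": "ncRNA", "3UTR": "3'UTR", "tRNA": "tRNA"}
    wb = Workbook()
    ws = wb.active
    ws.title = sheet_names.get(feature_code, feature_code)
    ws.append(PRIMER_COLUMNS)
    frame = primer_table_frame(primersets)
    for row in frame.itertuples(index=False):
        ws.append(list(row))
    wb.save(str(path))


def write_run_outputs(
    manifest: RunManifest,
    primersets: Sequence[PrimerSet],
    genome: Mapping[str, ChromosomeRecord],
    out_prefix: str | Path,
    end_region_len: int = 30,
    xlsx: bool = False,
) -> dict[str, Path]:
    """Write the full output triple (plus optional XLSX) for one run.

    Internal consistency between the manifest and the primer table is
    enforced before anything is written; on any failure partially written
    files are removed so a run never leaves a truncated primer database.
    """
    if manifest.feature_count != len(primersets):
        raise ReportError(
            f"manifest feature count {manifest.feature_count} != rows {len(primersets)}"
        )
    prefix = Path(out_prefix)
    paths = {
        "header": prefix.with_name(prefix.name + "_header.txt"),
        "primers": prefix.with_name(prefix.name + "_primers.tsv"),
        "check": prefix.with_name(prefix.name + "_check.tsv"),
    }
    if xlsx:
        paths["xlsx"] = prefix.with_name(prefix.name + "_primers.xlsx")
    written: list[Path] = []
    try:
        write_header_file(manifest, paths["header"])
        written.append(paths["header"])
        write_primer_table(primersets, paths["primers"])
        written.append(paths["primers"])
        write_check_file(primersets, genome, paths["check"], end_region_len)
        written.append(paths["check"])
        if xlsx:
            export_xlsx(primersets, manifest.feature_code, paths["xlsx"])
            written.append(paths["xlsx"])
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return paths
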